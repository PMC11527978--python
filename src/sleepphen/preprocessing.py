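"""Nightly records -> per-participant, per-window median feature samples.

Pipeline order: window extraction -> missingness filter -> rolling-mean
imputation -> per-window medians.  Winsorisation and z-scaling are deferred to
fold assembly (:mod:`sleepphen.folds`) because their statistics are fit on the
combined clinical + general-population matrix of each fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import FEATURES


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Windowing, exclusion, imputation and scaling settings.

    Defaults encode the analysis protocol: four consecutive 30-night windows
    over a 120-night span, exclusion of participants with >= 40% missing
    nights (>= 12 of 30) in any window, a centred 7-night rolling-mean
    imputation, and 5%/95% winsorisation before z-scaling.
    ``analysis_start_date=None`` anchors windows at each participant's first
    recorded night; a date fixes a common calendar anchor.
    """

    n_windows: int = 4
    window_len: int = 30
    missing_threshold: float = 0.4
    rolling_window: int = 7
    winsor_limits: tuple[float, float] = (0.05, 0.95)
    analysis_start_date: Optional[date] = None

    def __post_init__(self):
        if not 0.0 < self.missing_threshold <= 1.0:
            raise PreprocessingError("missing_threshold must lie in (0, 1]")
        lo, hi = self.winsor_limits
        if not 0.0 <= lo < hi <= 1.0:
            raise PreprocessingError("winsor_limits must satisfy 0 <= lo < hi <= 1")
        if self.n_windows < 1 or self.window_len < 1:
            raise PreprocessingError("n_windows and window_len must be positive")
        if self.rolling_window < 1:
            raise PreprocessingError("rolling_window must be positive")

    @property
    def span(self) -> int:
        return self.n_windows * self.window_len

    @property
    def exclusion_threshold(self) -> int:
        """Missing nights in any one window at/above which a participant is
        excluded: ceil(missing_threshold * window_len); 12 with defaults."""
        return math.ceil(self.missing_threshold * self.window_len)


def extract_windows(records: pd.DataFrame, config: PipelineConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Assign nights to consecutive half-open windows and count missing nights.

    Windows are [anchor + i*L, anchor + (i+1)*L) for i = 0..n_windows-1, with
    the anchor either ``config.analysis_start_date`` or the participant's
    first recorded night.  Nights outside the span are dropped.  A night is
    missing if its row is absent or all feature fields are NaN; per-window
    missing counts are ``window_len - observed``.

    Returns ``(windowed, counts, flagged)`` where ``windowed`` is the night
    table restricted to the span with a ``window_index`` column, ``counts``
    has one row per (participant, window) with ``n_missing``, and ``flagged``
    lists participants with zero nights in the span.
    """
    req = {"participant_id", "night_date", *FEATURES}
    if missing := req - set(records.columns):
        raise PreprocessingError(f"records missing columns: {sorted(missing)}")
    rec = records.copy()
    rec["night_date"] = pd.to_datetime(rec["night_date"])
    rec = rec.sort_values(["participant_id", "night_date"], kind="stable")

    if config.analysis_start_date is not None:
        anchor = pd.Timestamp(config.analysis_start_date)
        rec["_anchor"] = anchor
    else:
        rec["_anchor"] = rec.groupby("participant_id")["night_date"].transform("min")
    offset = (rec["night_date"] - rec["_anchor"]).dt.days
    rec["window_index"] = offset // config.window_len
    in_span = (offset >= 0) & (offset < config.span)

    flagged = sorted(set(rec.loc[~in_span, "participant_id"])
                     - set(rec.loc[in_span, "participant_id"]))
    windowed = rec.loc[in_span].drop(columns="_anchor").reset_index(drop=True)

    observed = windowed[list(FEATURES)].notna().any(axis=1)
    obs_counts = (windowed.assign(_obs=observed)
                  .groupby(["participant_id", "window_index"], sort=True)["_obs"]
                  .sum())
    pids = windowed["participant_id"].unique()
    full = pd.MultiIndex.from_product([pids, range(config.n_windows)],
                                      names=["participant_id", "window_index"])
    counts = obs_counts.reindex(full, fill_value=0).reset_index(name="n_observed")
    counts["n_missing"] = config.window_len - counts["n_observed"]
    return windowed, counts, flagged


def apply_missingness_filter(counts: pd.DataFrame, config: PipelineConfig
                             ) -> tuple[list[str], pd.DataFrame]:
    """Exclude participants with >= ceil(threshold * window_len) missing
    nights in any window; returns (retained ids, exclusion log)."""
    thr = config.exclusion_threshold
    worst = (counts.sort_values(["n_missing", "window_index"],
                                ascending=[False, True], kind="stable")
             .groupby("participant_id", sort=True).head(1))
    excluded = worst[worst["n_missing"] >= thr]
    log = excluded.rename(columns={"window_index": "offending_window"})[
        ["participant_id", "offending_window", "n_missing"]].reset_index(drop=True)
    retained = sorted(set(counts["participant_id"]) - set(log["participant_id"]))
    return retained, log


def impute_rolling_mean(windowed: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Fill absent nights with a centred rolling mean of observed values.

    Per participant and feature, each missing value is replaced by the mean of
    observed values within a centred window of ``rolling_window`` nights
    (edge-truncated).  If that window holds no observed value, the mean of the
    participant's observed values in the same 30-night window is used.
    Observed values are never altered.
    """
    out = windowed.sort_values(["participant_id", "night_date"], kind="stable").copy()
    feat = list(FEATURES)
    vals = out[feat]
    if vals.isna().any().any():
        by_pid = out.groupby("participant_id", sort=False)
        rolled = by_pid[feat].transform(
            lambda s: s.rolling(config.rolling_window, center=True,
                                min_periods=1).mean())
        filled = vals.fillna(rolled)
        if filled.isna().any().any():
            # rolling window held no observed night: fall back to the observed
            # mean of the participant's 30-night window, then the participant
            # mean over the whole span
            win_means = out.groupby(["participant_id", "window_index"],
                                    sort=False)[feat].transform("mean")
            filled = filled.fillna(win_means).fillna(by_pid[feat].transform("mean"))
        if filled.isna().any().any():
            bad = sorted(out.loc[filled.isna().any(axis=1), "participant_id"].unique())
            raise PreprocessingError(
                f"participants with a feature lacking any observed value: {bad}")
        out[feat] = filled
    return out.reset_index(drop=True)


def compute_window_medians(completed: pd.DataFrame,
                           counts: pd.DataFrame | None = None,
                           participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-feature median per (participant, window): the clustering unit.

    Optionally merges per-window missing-night counts and participant
    metadata (cohort).  Raises on empty windows.
    """
    if completed.empty:
        raise PreprocessingError("no nights to aggregate")
    med = (completed.groupby(["participant_id", "window_index"], sort=True)[list(FEATURES)]
           .median().reset_index())
    if counts is not None:
        med = med.merge(counts[["participant_id", "window_index", "n_missing"]],
                        on=["participant_id", "window_index"], how="left")
    if participants is not None:
        med = med.merge(participants[["participant_id", "cohort"]],
                        on="participant_id", how="left")
    return med


def winsorise(matrix: np.ndarray, limits: tuple[float, float]) -> np.ndarray:
    """Clip each column to its [lo, hi] quantiles (linear interpolation)."""
    X = np.asarray(matrix, dtype=float)
    lo, hi = limits
    ql = np.quantile(X, lo, axis=0)
    qh = np.quantile(X, hi, axis=0)
    return np.clip(X, ql, qh)


def zscore(matrix: np.ndarray) -> tuple[np.ndarray, dict]:
    """Column-wise standardisation to mean 0, SD 1 (population SD).

    Returns the transformed matrix and ``{"mean": mu, "sd": sd}`` for reuse;
    constant columns map to zeros with a warning (their stored sd is 1 so the
    transform stays invertible).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise PreprocessingError("z-scaling needs at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant column(s) mapped to zeros",
                      RuntimeWarning, stacklevel=2)
        sd = np.where(const, 1.0, sd)
    return (X - mu) / sd, {"mean": mu, "sd": sd}


def preprocess(records: pd.DataFrame, participants: pd.DataFrame,
               config: PipelineConfig
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run windowing -> filter -> imputation -> medians.

    Returns ``(window_samples, exclusions)``.  ``window_samples`` has one row
    per retained (participant, window) with the 10 median features, the
    missing-night count and cohort.
    """
    windowed, counts, flagged = extract_windows(records, config)
    retained, exclusions = apply_missingness_filter(counts, config)
    if flagged:
        exclusions = pd.concat(
            [exclusions,
             pd.DataFrame({"participant_id": flagged, "offending_window": -1,
                           "n_missing": config.span})],
            ignore_index=True)
    kept = windowed[windowed["participant_id"].isin(retained)]
    if kept.empty:
        raise PreprocessingError("no participants retained after missingness filter")
    completed = impute_rolling_mean(kept, config)
    samples = compute_window_medians(completed, counts, participants)
    return samples, exclusions
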