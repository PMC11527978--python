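"""Age-matched, disjoint general-population folds and per-fold matrices.

The clinical cohort is small and fixed; the general-population pool is large.
To compare like with like, each fold draws ``per_fold`` GP participants
without replacement (disjoint across folds), stratified so each fold's age
distribution matches the clinical cohort's binned age distribution.  The
fold's analysis matrix stacks the clinical window samples with the fold's GP
window samples, then winsorises and z-scales the combined matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import PipelineConfig, winsorise, zscore
from .synthetic import COHORT_GP, COHORT_PLWD, FEATURES


class FoldError(ValueError):
    pass


def default_age_bins() -> np.ndarray:
    """5-year bins covering ages 60-100 (edges 60, 65, ..., 100)."""
    return np.arange(60.0, 101.0, 5.0)


@dataclass(frozen=True)
class FoldPlan:
    n_folds: int = 5
    per_fold: int = 50
    age_bins: np.ndarray = field(default_factory=default_age_bins)
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "age_bins", np.asarray(self.age_bins, dtype=float))
        if self.n_folds < 1 or self.per_fold < 1:
            raise FoldError("n_folds and per_fold must be positive")
        if len(self.age_bins) < 2 or (np.diff(self.age_bins) <= 0).any():
            raise FoldError("age_bins must be strictly increasing edges")


@dataclass
class FoldDataset:
    """One fold's combined, winsorised, z-scaled analysis matrix."""

    fold_index: int
    matrix: np.ndarray                  # rows x 10, scaled
    metadata: pd.DataFrame              # row-aligned: participant_id, cohort, age, sex, window_index
    scaling: dict                       # {"mean", "sd"} from the combined fit


def _bin_ages(ages: np.ndarray, edges: np.ndarray) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if ages.size and ((ages < edges[0]) | (ages > edges[-1])).any():
        raise FoldError("ages fall outside the age-bin range")
    # right-open bins, last bin closed
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    return idx


def build_age_reference(plwd_participants: pd.DataFrame,
                        age_bins: np.ndarray) -> np.ndarray:
    """Per-bin proportions of the clinical cohort's ages (sums to 1)."""
    if plwd_participants.empty:
        raise FoldError("reference cohort is empty")
    edges = np.asarray(age_bins, dtype=float)
    idx = _bin_ages(plwd_participants["age"].to_numpy(), edges)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return counts / counts.sum()


def _quotas(per_fold: int, reference: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of per_fold * reference; ties by bin order."""
    raw = per_fold * np.asarray(reference, dtype=float)
    base = np.floor(raw).astype(int)
    short = per_fold - base.sum()
    frac = raw - base
    # stable argsort descending on fraction -> ties broken by bin order
    order = np.argsort(-frac, kind="stable")
    base[order[:short]] += 1
    return base


def sample_folds(gp_pool: pd.DataFrame, reference: np.ndarray,
                 plan: FoldPlan) -> list[list[str]]:
    """Draw ``n_folds`` disjoint age-matched GP participant-id sets.

    Per fold and age bin, quotas are ``per_fold * reference`` with
    largest-remainder rounding; draws are uniform without replacement within
    bins (and across folds unless ``plan.with_replacement``).  Raises naming
    the first bin whose pool is insufficient.
    """
    rng = np.random.default_rng(plan.seed)
    edges = plan.age_bins
    pool_ids = list(gp_pool["participant_id"])
    if not plan.with_replacement and plan.n_folds * plan.per_fold == len(pool_ids):
        # exhaustive pool: every member is used exactly once, so age quotas
        # cannot bind; partition uniformly at random
        perm = rng.permutation(len(pool_ids))
        return [[pool_ids[i] for i in perm[f * plan.per_fold:(f + 1) * plan.per_fold]]
                for f in range(plan.n_folds)]
    quotas = _quotas(plan.per_fold, reference)
    bins = _bin_ages(gp_pool["age"].to_numpy(), edges)
    pools = {b: list(gp_pool["participant_id"].to_numpy()[bins == b])
             for b in range(len(edges) - 1)}
    folds: list[list[str]] = []
    for f in range(plan.n_folds):
        chosen: list[str] = []
        for b, q in enumerate(quotas):
            if q == 0:
                continue
            pool = pools[b]
            if len(pool) < q:
                raise FoldError(
                    f"fold {f}: age bin [{edges[b]:g}, {edges[b + 1]:g}) needs "
                    f"{q} participants but only {len(pool)} remain in the pool")
            take = rng.choice(len(pool), size=q, replace=False)
            picked = [pool[i] for i in sorted(take)]
            chosen.extend(picked)
            if not plan.with_replacement:
                pools[b] = [p for i, p in enumerate(pool) if i not in set(take)]
        folds.append(chosen)
    return folds


def assemble_fold(plwd_samples: pd.DataFrame, gp_samples: pd.DataFrame,
                  config: PipelineConfig, participants: pd.DataFrame,
                  fold_index: int = 0) -> FoldDataset:
    """Stack clinical + fold GP window samples; winsorise and z-scale combined.

    Both inputs are window-sample tables from :func:`sleepphen.preprocessing.
    preprocess`.  Scaling statistics are fit on the combined matrix, not per
    cohort, and are returned for reuse.
    """
    for df, name in ((plwd_samples, "plwd_samples"), (gp_samples, "gp_samples")):
        if not df.empty and (missing := set(FEATURES) - set(df.columns)):
            raise FoldError(f"{name} missing feature columns: {sorted(missing)}")
    combined = pd.concat([plwd_samples, gp_samples], ignore_index=True)
    if combined.empty:
        raise FoldError("no samples to assemble")
    meta = combined[["participant_id", "window_index"]].copy()
    meta = meta.merge(participants[["participant_id", "cohort", "age", "sex"]],
                      on="participant_id", how="left")
    X = combined[list(FEATURES)].to_numpy(dtype=float)
    Xw = winsorise(X, config.winsor_limits)
    Z, scaling = zscore(Xw)
    return FoldDataset(fold_index=fold_index, matrix=Z,
                       metadata=meta.reset_index(drop=True), scaling=scaling)


def build_folds(window_samples: pd.DataFrame, participants: pd.DataFrame,
                plan: FoldPlan, config: PipelineConfig) -> list[FoldDataset]:
    """End-to-end fold construction from a combined window-sample table."""
    plwd_ids = set(participants.loc[participants["cohort"] == COHORT_PLWD,
                                    "participant_id"])
    retained = set(window_samples["participant_id"])
    plwd_samples = window_samples[window_samples["participant_id"].isin(plwd_ids)]
    gp_part = participants[(participants["cohort"] == COHORT_GP)
                           & participants["participant_id"].isin(retained)]
    reference = build_age_reference(
        participants[participants["participant_id"].isin(plwd_ids & retained)],
        plan.age_bins)
    fold_ids = sample_folds(gp_part, reference, plan)
    datasets = []
    for f, ids in enumerate(fold_ids):
        gp_samples = window_samples[window_samples["participant_id"].isin(ids)]
        datasets.append(assemble_fold(plwd_samples, gp_samples, config,
                                      participants, fold_index=f))
    return datasets
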