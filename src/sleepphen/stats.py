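"""Cluster demographic profiles and statistical comparisons.

Profiles report, per harmonized cluster, the cohort and sex percentages and
mean age of its member rows, averaged across folds with the SEM (sample SD of
the five fold values over sqrt(number of folds)).  Comparisons use one-way
ANOVA with Tukey's post-hoc (Tukey–Kramer for unequal n), independent
t-tests, and a two-way mixed-design (repeated-measures) ANOVA with cluster as
the between-subject factor and sleep metric as the within-subject factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import COHORT_GP, COHORT_PLWD


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple
    pvalue: float
    pairwise: Optional[pd.DataFrame] = None


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.nan, np.nan
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def profile_clusters(assignments: pd.DataFrame,
                     participants: pd.DataFrame,
                     n_folds: int | None = None) -> pd.DataFrame:
    """Aggregate per-cluster demographics across folds.

    ``assignments`` needs columns fold, participant_id, cluster (harmonized);
    cohort/sex/age are taken from ``participants``.  Per fold and cluster the
    cohort %, sex % and mean age are computed over the cluster's rows, then
    averaged across folds with SEM.  A cluster absent from a fold contributes
    no value for that fold (the SEM denominator shrinks accordingly).
    """
    req = {"fold", "participant_id", "cluster"}
    if missing := req - set(assignments.columns):
        raise StatsError(f"assignments missing columns: {sorted(missing)}")
    df = assignments.drop(
        columns=[c for c in ("cohort", "sex", "age") if c in assignments.columns]
    ).merge(participants[["participant_id", "cohort", "sex", "age"]],
            on="participant_id", how="left")
    per_fold = (df.groupby(["fold", "cluster"])
                .agg(pct_plwd=("cohort", lambda c: 100.0 * (c == COHORT_PLWD).mean()),
                     pct_female=("sex", lambda s: 100.0 * (s == "F").mean()),
                     mean_age=("age", "mean"),
                     n=("participant_id", "size"))
                .reset_index())
    per_fold["pct_gp"] = 100.0 - per_fold["pct_plwd"]
    per_fold["pct_male"] = 100.0 - per_fold["pct_female"]
    rows = []
    for cluster, grp in per_fold.groupby("cluster"):
        row = {"cluster": cluster, "n_folds_present": len(grp),
               "n_per_fold": list(grp["n"])}
        for col in ("pct_plwd", "pct_gp", "pct_male", "pct_female", "mean_age"):
            m, sem = _mean_sem(grp[col].to_numpy())
            row[col] = m
            row[f"{col}_sem"] = sem
        rows.append(row)
    return pd.DataFrame(rows)


def profile_features(assignments: pd.DataFrame, feature_columns: Sequence[str]
                     ) -> pd.DataFrame:
    """Per-cluster scaled feature means +/- SEM across folds."""
    per_fold = (assignments.groupby(["fold", "cluster"])[list(feature_columns)]
                .mean().reset_index())
    rows = []
    for cluster, grp in per_fold.groupby("cluster"):
        row = {"cluster": cluster}
        for col in feature_columns:
            m, sem = _mean_sem(grp[col].to_numpy())
            row[col] = m
            row[f"{col}_sem"] = sem
        rows.append(row)
    return pd.DataFrame(rows)


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> StatResult:
    """One-way ANOVA: F = MS_between / MS_within with df (k-1, N-k).

    All-identical groups return F = 0, p = 1; zero within-group variance with
    distinct means returns F = inf, p = 0.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise StatsError("each group needs at least 2 values")
    n = len(values)
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df = (len(uniq) - 1, n - len(uniq))
    if ssb == 0.0:
        return StatResult("one_way_anova", 0.0, df, 1.0)
    if ssw == 0.0:
        return StatResult("one_way_anova", float("inf"), df, 0.0)
    F = (ssb / df[0]) / (ssw / df[1])
    p = float(sps.f.sf(F, *df))
    return StatResult("one_way_anova", float(F), df, p)


def tukey_hsd(values: np.ndarray, groups: np.ndarray,
              alpha: float = 0.05) -> StatResult:
    """All pairwise mean comparisons with studentized-range adjusted p-values
    (Tukey–Kramer under unequal group sizes)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(np.unique(groups))
    if len(uniq) < 2:
        raise StatsError("Tukey HSD needs at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    res = sps.tukey_hsd(*samples)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            rows.append({"group_a": uniq[i], "group_b": uniq[j],
                         "mean_diff": float(res.statistic[i, j]),
                         "p_adj": float(res.pvalue[i, j]),
                         "ci_low": float(ci.low[i, j]),
                         "ci_high": float(ci.high[i, j])})
    pairwise = pd.DataFrame(rows)
    best = pairwise.loc[pairwise["p_adj"].idxmin()]
    return StatResult("tukey_hsd", float(best["mean_diff"]),
                      (len(uniq), len(values) - len(uniq)),
                      float(best["p_adj"]), pairwise)


def t_test_independent(a: np.ndarray, b: np.ndarray,
                       welch: bool = False) -> StatResult:
    """Two-sided independent-samples t-test (pooled variance by default,
    Welch when requested)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(res.statistic):  # identical constant samples
        return StatResult("t_test_independent", 0.0, (float(res.df),), 1.0)
    return StatResult("t_test_independent", float(res.statistic),
                      (float(res.df),), float(res.pvalue))


def two_way_rm_anova(data: pd.DataFrame, dv: str, between: str, within: str,
                     subject: str) -> dict[str, StatResult]:
    """Two-way mixed-design ANOVA (between-subject x repeated within-subject).

    Sum-of-squares partition: the between-groups effect is tested against
    subject-within-groups variation; the within (repeated) main effect and
    the interaction are tested against the subject-by-within residual.
    Every subject must have exactly one value per within level; with a single
    within level the between effect collapses exactly to the one-way ANOVA on
    subject values.  Returns ``{"between", "within", "interaction"}``.
    """
    for col in (dv, between, within, subject):
        if col not in data.columns:
            raise StatsError(f"column {col!r} not in data")
    levels = np.sort(data[within].unique())
    b = len(levels)
    cover = data.groupby(subject)[within].agg(lambda s: len(set(s)))
    sizes = data.groupby(subject)[within].size()
    bad = sorted(cover[(cover != b) | (sizes != b)].index)
    if bad:
        raise StatsError(f"subjects without one value per within level: {bad}")
    grp_of = data.groupby(subject)[between].first()
    if (data.groupby(subject)[between].nunique() > 1).any():
        raise StatsError("subjects must be nested in a single between group")
    a = grp_of.nunique()
    if a < 2:
        raise StatsError("need at least 2 between-subject groups")
    N = len(grp_of)

    y = data[dv].astype(float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_mean = data.groupby(subject)[dv].mean()
    grp_mean = data.groupby(between)[dv].mean()
    n_g = grp_of.value_counts()
    ss_between = b * sum(n_g[g] * (grp_mean[g] - grand) ** 2 for g in grp_mean.index)
    ss_subj = b * ((subj_mean - grp_of.map(grp_mean)) ** 2).sum()
    lvl_mean = data.groupby(within)[dv].mean()
    ss_within = N * ((lvl_mean - grand) ** 2).sum()
    cell = data.groupby([between, within])[dv].mean()
    ss_cells = sum(n_g[g] * (cell[g, l] - grand) ** 2
                   for g in grp_mean.index for l in levels)
    ss_inter = ss_cells - ss_between - ss_within
    ss_err = ss_total - ss_cells - ss_subj

    df_between = a - 1
    df_subj = N - a
    df_within = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = (N - a) * (b - 1)

    def _f(ss_eff, df_eff, ss_e, df_e, name):
        ss_eff = max(float(ss_eff), 0.0)  # guard tiny negative cancellation
        if df_eff == 0:
            return StatResult(name, 0.0, (df_eff, df_e), 1.0)
        ms_eff = ss_eff / df_eff
        if df_e == 0 or ss_e == 0.0:
            if ms_eff == 0.0:
                return StatResult(name, 0.0, (df_eff, df_e), 1.0)
            return StatResult(name, float("inf"), (df_eff, df_e), 0.0)
        F = ms_eff / (ss_e / df_e)
        return StatResult(name, float(F), (df_eff, df_e),
                          float(sps.f.sf(F, df_eff, df_e)))

    return {
        "between": _f(ss_between, df_between, ss_subj, df_subj, "rm_anova_between"),
        "within": _f(ss_within, df_within, ss_err, df_err, "rm_anova_within"),
        "interaction": _f(ss_inter, df_inter, ss_err, df_err, "rm_anova_interaction"),
    }


def mmse_by_cluster(assignments: pd.DataFrame,
                    participants: pd.DataFrame) -> StatResult:
    """One-way ANOVA of MMSE across harmonized clusters, clinical rows only."""
    df = assignments.drop(
        columns=[c for c in ("cohort", "mmse") if c in assignments.columns]
    ).merge(participants[["participant_id", "cohort", "mmse"]],
            on="participant_id", how="left")
    df = df[(df["cohort"] == COHORT_PLWD) & df["mmse"].notna()]
    if df.empty:
        raise StatsError("no clinical rows with MMSE scores")
    return one_way_anova(df["mmse"].to_numpy(float),
                         df["cluster"].to_numpy())
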