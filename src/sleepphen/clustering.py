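"""Cluster model fitting, internal validity indices, model selection and
cross-fold label harmonisation.

Three algorithm families are compared: K-means (centroid-based), Gaussian
mixtures (distribution-based) and Ward agglomerative clustering
(hierarchical).  Because no ground-truth labels exist, models are ranked by
internal indices — Silhouette Coefficient (SC, higher better), Calinski–
Harabasz (CH, higher better) and Davies–Bouldin (DB, lower better) — each
summarised over bootstrap refits with percentile confidence intervals.
Cluster labels are made comparable across folds by sorting centroids by their
Euclidean distance to the origin of the z-scaled feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

ALGORITHMS = ("kmeans", "gmm", "agglomerative")


class ClusteringError(ValueError):
    pass


class DegenerateClusteringError(ClusteringError):
    """Raised when an index is undefined (e.g. coincident centroids)."""


@dataclass
class ClusterResult:
    algorithm: str
    k: int
    labels: np.ndarray           # per-row label in 0..k-1
    centroids: np.ndarray        # k x d, mean of member rows for all algorithms
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        uniq = np.unique(self.labels)
        if len(uniq) != self.k or uniq.min() < 0 or uniq.max() >= self.k:
            raise ClusteringError(
                f"labels must cover 0..{self.k - 1} with no empty cluster")


@dataclass
class MetricSummary:
    algorithm: str
    k: int
    sc: float
    ch: float
    db: float
    sc_boot_mean: float
    sc_lo: float
    sc_hi: float
    ch_boot_mean: float
    ch_lo: float
    ch_hi: float
    db_boot_mean: float
    db_lo: float
    db_hi: float
    n_runs: int


def _member_means(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    return np.vstack([X[labels == c].mean(axis=0) for c in range(k)])


def _check_fit_inputs(X: np.ndarray, k: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ClusteringError("k must be >= 2")
    if k > X.shape[0]:
        raise ClusteringError(f"k={k} exceeds {X.shape[0]} rows")
    return X


def fit_kmeans(X: np.ndarray, k: int, seed: int | None = 0) -> ClusterResult:
    """Lloyd's algorithm with k-means++ init, 10 restarts, tol 1e-4."""
    X = _check_fit_inputs(X, k)
    km = KMeans(n_clusters=k, n_init=10, tol=1e-4, random_state=seed).fit(X)
    return ClusterResult("kmeans", k, km.labels_,
                         _member_means(X, km.labels_, k), seed)


def fit_gmm(X: np.ndarray, k: int, seed: int | None = 0) -> ClusterResult:
    """Full-covariance Gaussian mixture (EM, reg_covar 1e-6); hard labels by
    maximum responsibility; centroids are member means, not component means,
    so harmonisation treats all algorithms alike."""
    X = _check_fit_inputs(X, k)
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         reg_covar=1e-6, n_init=3, random_state=seed).fit(X)
    labels = gm.predict(X)
    if len(np.unique(labels)) < k:
        raise ClusteringError(f"GMM produced an empty cluster at k={k}")
    return ClusterResult("gmm", k, labels, _member_means(X, labels, k), seed)


def fit_agglomerative(X: np.ndarray, k: int, seed: int | None = None) -> ClusterResult:
    """Ward-linkage agglomerative clustering cut at k (fully deterministic)."""
    X = _check_fit_inputs(X, k)
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    return ClusterResult("agglomerative", k, labels, _member_means(X, labels, k))


_FITTERS = {"kmeans": fit_kmeans, "gmm": fit_gmm, "agglomerative": fit_agglomerative}


def fit(algorithm: str, X: np.ndarray, k: int, seed: int | None = 0) -> ClusterResult:
    try:
        fitter = _FITTERS[algorithm]
    except KeyError:
        raise ClusteringError(f"unknown algorithm {algorithm!r}; "
                              f"choose from {ALGORITHMS}") from None
    return fitter(X, k, seed)


# ---------------------------------------------------------------------------
# Internal validity indices.  Implemented directly (exact Euclidean distances
# via scipy.spatial.distance.cdist) rather than through scikit-learn's
# metric functions: sklearn's quadratic-expansion distance shortcut loses
# ~1e-8 of precision, and this package pins its own edge conventions.
# ---------------------------------------------------------------------------

def _check_index_inputs(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ClusteringError("matrix and labels disagree on row count")
    k = len(np.unique(labels))
    if k < 2:
        raise ClusteringError("indices need at least 2 clusters")
    return X, labels, k


def silhouette_score(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s_i = (b_i - a_i)/max(a_i, b_i); singleton-cluster
    points score 0, and the all-singleton partition scores 0."""
    X, labels, k = _check_index_inputs(X, labels)
    n = X.shape[0]
    if k == n:
        return 0.0
    D = cdist(X, X)
    uniq = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in uniq])
    sums = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    own = labels[:, None] == uniq[None, :]
    own_count = counts[own.argmax(axis=1)]
    s = np.zeros(n)
    nonsing = own_count > 1
    a = sums[own] / np.maximum(own_count - 1, 1)
    b = np.min(np.where(own, np.inf, sums / counts), axis=1)
    s[nonsing] = ((b - a) / np.maximum(a, b))[nonsing]
    return float(s.mean())


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio normalised by (k-1, n-k) degrees of
    freedom; +inf when the within-cluster scatter is exactly zero."""
    X, labels, k = _check_index_inputs(X, labels)
    n = X.shape[0]
    if k == n:
        raise ClusteringError("Calinski-Harabasz undefined for k = n")
    mu = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in np.unique(labels):
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        between += len(Xc) * ((mc - mu) ** 2).sum()
        within += ((Xc - mc) ** 2).sum()
    if within == 0.0:
        return float("inf")
    return float((between / (k - 1)) / (within / (n - k)))


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst (S_c + S_c')/dist(mu_c, mu_c') ratio;
    raises :class:`DegenerateClusteringError` on coincident centroids."""
    X, labels, k = _check_index_inputs(X, labels)
    uniq = np.unique(labels)
    cents = np.vstack([X[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array([cdist(X[labels == c], cents[i:i + 1]).mean()
                        for i, c in enumerate(uniq)])
    dist = cdist(cents, cents)
    np.fill_diagonal(dist, np.inf)
    if (dist <= 0).any():
        raise DegenerateClusteringError("coincident cluster centroids")
    R = (scatter[:, None] + scatter[None, :]) / dist
    return float(R.max(axis=1).mean())


def bootstrap_metric_ci(X: np.ndarray, algorithm: str, k: int,
                        n_runs: int = 15, seed: int | None = 0,
                        ci_level: float = 0.95, retry_cap: int = 10
                        ) -> MetricSummary:
    """Point indices on the full data plus bootstrap mean and percentile CI.

    Each run resamples rows with replacement (same n), refits, and evaluates
    SC/CH/DB on the resample.  Runs yielding an empty cluster (or fewer than
    k distinct rows) are redrawn, up to ``retry_cap`` attempts per run.
    """
    if n_runs < 2:
        raise ClusteringError("n_runs must be >= 2")
    X = _check_fit_inputs(X, k)
    rng = np.random.default_rng(seed)
    point = fit(algorithm, X, k, seed)
    sc_p = silhouette_score(X, point.labels)
    ch_p = calinski_harabasz(X, point.labels)
    db_p = davies_bouldin(X, point.labels)
    n = X.shape[0]
    runs = np.empty((n_runs, 3))
    for r in range(n_runs):
        for attempt in range(retry_cap):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if len(np.unique(Xb, axis=0)) < k:
                continue
            try:
                res = fit(algorithm, Xb, k,
                          seed=int(rng.integers(0, 2 ** 31)))
                runs[r] = (silhouette_score(Xb, res.labels),
                           calinski_harabasz(Xb, res.labels),
                           davies_bouldin(Xb, res.labels))
                break
            except ClusteringError:
                continue
        else:
            raise ClusteringError(
                f"bootstrap run for {algorithm} k={k} failed {retry_cap} times")
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(runs, alpha, axis=0)
    hi = np.quantile(runs, 1.0 - alpha, axis=0)
    mean = runs.mean(axis=0)
    return MetricSummary(algorithm, k, sc_p, ch_p, db_p,
                         mean[0], lo[0], hi[0],
                         mean[1], lo[1], hi[1],
                         mean[2], lo[2], hi[2], n_runs)


def sweep_models(X: np.ndarray, algorithms=ALGORITHMS,
                 k_range: tuple[int, int] = (2, 25), n_runs: int = 15,
                 seed: int | None = 0) -> pd.DataFrame:
    """Full (algorithm, k) grid of bootstrap metric summaries."""
    X = np.asarray(X, dtype=float)
    k_min, k_max = k_range
    if k_max > X.shape[0] - 1:
        logger.warning("k_max=%d truncated to n-1=%d", k_max, X.shape[0] - 1)
        k_max = X.shape[0] - 1
    ss = np.random.SeedSequence(seed)
    rows = []
    for alg in algorithms:
        for k in range(k_min, k_max + 1):
            sub = int(ss.spawn(1)[0].generate_state(1)[0] % 2 ** 31)
            rows.append(bootstrap_metric_ci(X, alg, k, n_runs=n_runs, seed=sub))
    return pd.DataFrame([vars(r) for r in rows])


def select_model(table: pd.DataFrame,
                 sc_tol: float = 0.005) -> tuple[str, int, pd.DataFrame]:
    """Pick the winner: highest SC; ties by higher CH, then lower DB.

    Continuous scores never tie exactly, so rows whose SC lies within
    ``sc_tol`` of the maximum count as tied (0.005 is half a unit of the
    two-decimal precision such scores are conventionally reported at) and
    are ranked by CH, then DB.  Remaining ties (identical partitions under
    different algorithms) resolve by the order algorithms appear in the
    table.  Returns ``(algorithm, k, audit)`` where ``audit`` is the table
    sorted by rank.
    """
    if table.empty:
        raise ClusteringError("empty selection table")
    audit = table.sort_values(["sc", "ch", "db"],
                              ascending=[False, False, True],
                              kind="stable").reset_index(drop=True)
    tied = table[table["sc"] >= table["sc"].max() - sc_tol]
    best = tied.sort_values(["ch", "db"], ascending=[False, True],
                            kind="stable").iloc[0]
    return str(best["algorithm"]), int(best["k"]), audit


def harmonize_labels(centroids_per_fold: list[np.ndarray],
                     ascending: bool = True) -> list[np.ndarray]:
    """Per-fold relabeling maps sorting clusters by centroid-origin distance.

    ``maps[f][old_label] = harmonized label`` with harmonized labels 1..k,
    label 1 going to the smallest norm when ``ascending`` (flag to invert).
    Tied norms break deterministically by first centroid coordinate (logged).
    """
    ks = {c.shape[0] for c in centroids_per_fold}
    if len(ks) != 1:
        raise ClusteringError(f"folds disagree on k: {sorted(ks)}")
    maps = []
    for f, cents in enumerate(centroids_per_fold):
        cents = np.asarray(cents, dtype=float)
        norms = np.linalg.norm(cents, axis=1)
        if len(np.unique(norms)) < len(norms):
            logger.warning("fold %d: tied centroid norms, breaking ties by "
                           "first coordinate", f)
        order = np.lexsort((cents[:, 0], norms))  # norm, then first coordinate
        if not ascending:
            order = order[::-1]
        mapping = np.empty(len(norms), dtype=int)
        mapping[order] = np.arange(1, len(norms) + 1)
        maps.append(mapping)
    return maps


def apply_harmonization(labels: np.ndarray, mapping: np.ndarray) -> np.ndarray:
    """Translate raw 0-based labels to harmonized 1-based labels."""
    return np.asarray(mapping)[np.asarray(labels)]
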