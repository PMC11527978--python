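"""Cluster fits, validity indices vs brute-force oracles, selection,
harmonisation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from sleepphen import (ClusteringError, DegenerateClusteringError,
                       apply_harmonization, bootstrap_metric_ci,
                       calinski_harabasz, davies_bouldin, fit_agglomerative,
                       fit_gmm, fit_kmeans, harmonize_labels, select_model,
                       silhouette_score, sweep_models)


# --- independent O(n^2) / direct-formula oracles ---------------------------

def silhouette_oracle(X, labels):
    n = len(X)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s[i] = 0.0
            continue
        a = np.mean([dist[i, j] for j in own])
        b = min(np.mean([dist[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s.mean()


def ch_oracle(X, labels):
    n, k = len(X), len(set(labels))
    mu = X.mean(0)
    ssb = sum((labels == c).sum() * ((X[labels == c].mean(0) - mu) ** 2).sum()
              for c in set(labels))
    ssw = sum(((X[labels == c] - X[labels == c].mean(0)) ** 2).sum()
              for c in set(labels))
    return (ssb / (k - 1)) / (ssw / (n - k))


def db_oracle(X, labels):
    cs = sorted(set(labels))
    mus = {c: X[labels == c].mean(0) for c in cs}
    S = {c: np.mean(np.sqrt(((X[labels == c] - mus[c]) ** 2).sum(1))) for c in cs}
    total = 0.0
    for c in cs:
        total += max((S[c] + S[d]) / np.linalg.norm(mus[c] - mus[d])
                     for d in cs if d != c)
    return total / len(cs)


def random_instance(rng, n_max=20, k_max=4):
    n = int(rng.integers(5, n_max + 1))
    d = int(rng.integers(2, 6))
    k = int(rng.integers(2, min(k_max, n - 1) + 1))
    X = rng.normal(size=(n, d))
    while True:
        labels = rng.integers(0, k, size=n)
        if len(set(labels)) == k:
            return X, labels


class TestIndices:
    def test_duplicated_tight_clusters_score_one(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0], [10.0, 10.0]])
        labels = np.array([0, 0, 1, 1])
        assert silhouette_score(X, labels) == pytest.approx(1.0)
        assert davies_bouldin(X, labels) == pytest.approx(0.0)
        assert calinski_harabasz(X, labels) == np.inf

    def test_all_singletons_silhouette_zero(self):
        X = np.arange(8.0).reshape(4, 2)
        assert silhouette_score(X, np.arange(4)) == 0.0
        with pytest.raises(ClusteringError):
            calinski_harabasz(X, np.arange(4))

    def test_single_cluster_rejected(self):
        X = np.arange(8.0).reshape(4, 2)
        for fn in (silhouette_score, calinski_harabasz, davies_bouldin):
            with pytest.raises(ClusteringError):
                fn(X, np.zeros(4, dtype=int))

    def test_db_coincident_centroids_degenerate(self):
        X = np.array([[0.0, 1.0], [0.0, -1.0], [1.0, 0.0], [-1.0, 0.0]])
        labels = np.array([0, 0, 1, 1])  # both centroids at the origin
        with pytest.raises(DegenerateClusteringError):
            davies_bouldin(X, labels)

    def test_label_permutation_invariance(self, rng):
        X, labels = random_instance(rng)
        perm = rng.permutation(len(set(labels)))
        relabeled = perm[labels]
        for fn in (silhouette_score, calinski_harabasz, davies_bouldin):
            assert fn(X, labels) == pytest.approx(fn(X, relabeled), abs=1e-12)

    def test_rotation_invariance(self, rng):
        X, labels = random_instance(rng)
        Q = ortho_group.rvs(X.shape[1], random_state=7)
        for fn in (silhouette_score, calinski_harabasz, davies_bouldin):
            assert fn(X, labels) == pytest.approx(fn(X @ Q, labels), abs=1e-9)

    def test_indices_match_oracles_on_random_instances(self, rng):
        for _ in range(40):
            X, labels = random_instance(rng)
            assert silhouette_score(X, labels) == pytest.approx(
                silhouette_oracle(X, labels), abs=1e-10)
            assert calinski_harabasz(X, labels) == pytest.approx(
                ch_oracle(X, labels), abs=1e-10, rel=1e-10)
            assert davies_bouldin(X, labels) == pytest.approx(
                db_oracle(X, labels), abs=1e-10, rel=1e-10)


class TestFits:
    def test_kmeans_saturated_k(self, rng):
        X = rng.normal(size=(6, 3))
        res = fit_kmeans(X, 6, seed=0)
        assert sorted(res.labels) == list(range(6))
        np.testing.assert_allclose(np.sort(res.centroids, axis=0),
                                   np.sort(X, axis=0))

    def test_kmeans_separable_groups(self):
        X = np.vstack([np.zeros((5, 4)), np.full((5, 4), 9.0)])
        X += np.linspace(0, 0.01, 40).reshape(10, 4)
        res = fit_kmeans(X, 2, seed=0)
        assert len(set(res.labels[:5])) == 1
        assert res.labels[0] != res.labels[5]

    def test_kmeans_beats_every_bipartition_of_toy(self, rng):
        # exhaustive oracle: global min within-cluster SSE over all 2-part
        # partitions of 12 points
        X = rng.normal(size=(12, 2))
        res = fit_kmeans(X, 2, seed=0)
        sse = sum(((X[res.labels == c] - X[res.labels == c].mean(0)) ** 2).sum()
                  for c in (0, 1))
        best = np.inf
        for bits in range(1, 2 ** 11):
            mask = np.array([(bits >> i) & 1 for i in range(12)], dtype=bool)
            mask[-1] = False  # fix point 12 in group 0 (symmetry)
            if mask.all() or not mask.any():
                continue
            cand = (((X[mask] - X[mask].mean(0)) ** 2).sum()
                    + ((X[~mask] - X[~mask].mean(0)) ** 2).sum())
            best = min(best, cand)
        assert sse <= best + 1e-9

    def test_gmm_and_agglomerative_recover_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 3)), rng.normal(5, 0.3, (20, 3))])
        truth = np.repeat([0, 1], 20)
        for fitter in (fit_gmm, fit_agglomerative):
            res = fitter(X, 2, 0)
            agree = max((res.labels == truth).mean(),
                        (res.labels == 1 - truth).mean())
            assert agree == 1.0

    def test_agglomerative_k_equals_n(self, rng):
        X = rng.normal(size=(7, 2))
        res = fit_agglomerative(X, 7)
        assert sorted(res.labels) == list(range(7))

    def test_ward_merge_sequence_matches_greedy_oracle(self, rng):
        # greedy minimal-variance-increase merges on a 6-point toy
        X = rng.normal(size=(6, 2))
        clusters = [[i] for i in range(6)]
        partitions = {}
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(range(len(clusters)), 2):
                merged = clusters[a] + clusters[b]
                inc = (((X[merged] - X[merged].mean(0)) ** 2).sum()
                       - ((X[clusters[a]] - X[clusters[a]].mean(0)) ** 2).sum()
                       - ((X[clusters[b]] - X[clusters[b]].mean(0)) ** 2).sum())
                if best is None or inc < best[0]:
                    best = (inc, a, b)
            _, a, b = best
            clusters = ([c for i, c in enumerate(clusters) if i not in (a, b)]
                        + [clusters[a] + clusters[b]])
            partitions[len(clusters)] = [sorted(c) for c in clusters]
        for k in (2, 3, 4, 5):
            res = fit_agglomerative(X, k)
            got = sorted(sorted(np.flatnonzero(res.labels == c).tolist())
                         for c in range(k))
            assert got == sorted(partitions[k])

    def test_kmeans_inertia_non_increasing_over_lloyd_iterations(self, rng):
        from sklearn.cluster import KMeans
        X = rng.normal(size=(60, 4))
        init = X[:3]
        inertias = [KMeans(3, init=init, n_init=1, max_iter=it, tol=0.0)
                    .fit(X).inertia_ for it in range(1, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_k_exceeding_rows_rejected(self, rng):
        with pytest.raises(ClusteringError):
            fit_kmeans(rng.normal(size=(3, 2)), 4)


class TestBootstrapAndSweep:
    def test_ci_ordering_and_shape(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (20, 3)), rng.normal(6, 0.5, (20, 3))])
        ms = bootstrap_metric_ci(X, "kmeans", 2, n_runs=15, seed=1)
        assert ms.n_runs == 15
        for m in ("sc", "ch", "db"):
            lo, mid, hi = (getattr(ms, f"{m}_lo"), getattr(ms, f"{m}_boot_mean"),
                           getattr(ms, f"{m}_hi"))
            assert lo <= mid <= hi

    def test_duplicated_groups_give_zero_width_ci(self):
        X = np.vstack([np.zeros((20, 2)), np.full((20, 2), 5.0)])
        ms = bootstrap_metric_ci(X, "kmeans", 2, n_runs=5, seed=0)
        assert ms.sc_lo == ms.sc_hi == 1.0
        assert ms.db_lo == ms.db_hi == 0.0

    def test_sweep_grid_shape(self, rng):
        X = rng.normal(size=(30, 3))
        tbl = sweep_models(X, algorithms=("kmeans",), k_range=(2, 2),
                           n_runs=2, seed=0)
        assert len(tbl) == 1
        tbl = sweep_models(X, algorithms=("kmeans", "agglomerative"),
                           k_range=(2, 4), n_runs=2, seed=0)
        assert len(tbl) == 6
        assert set(tbl["algorithm"]) == {"kmeans", "agglomerative"}

    def test_sweep_truncates_k_beyond_n(self, rng):
        X = rng.normal(size=(8, 2))
        tbl = sweep_models(X, algorithms=("agglomerative",), k_range=(2, 25),
                           n_runs=2, seed=0)
        assert tbl["k"].max() == 7


class TestSelectModel:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["algorithm", "k", "sc", "ch", "db"])

    def test_single_row(self):
        tbl = self.make_table([("kmeans", 3, 0.2, 30.0, 1.5)])
        assert select_model(tbl)[:2] == ("kmeans", 3)

    def test_sc_ranking(self):
        tbl = self.make_table([("kmeans", 3, 0.183, 34.06, 1.77),
                               ("gmm", 3, 0.122, 40.70, 1.96),
                               ("agglomerative", 3, 0.142, 27.49, 1.95)])
        alg, k, audit = select_model(tbl)
        assert (alg, k) == ("kmeans", 3)
        assert list(audit["algorithm"]) == ["kmeans", "agglomerative", "gmm"]

    def test_ch_tiebreak_then_db(self):
        tbl = self.make_table([("gmm", 2, 0.5, 200.0, 1.0),
                               ("kmeans", 2, 0.5, 300.0, 1.2)])
        assert select_model(tbl)[:2] == ("kmeans", 2)
        tbl = self.make_table([("gmm", 2, 0.5, 300.0, 1.4),
                               ("kmeans", 2, 0.5, 300.0, 1.2)])
        assert select_model(tbl)[:2] == ("kmeans", 2)

    def test_empty_rejected(self):
        with pytest.raises(ClusteringError):
            select_model(pd.DataFrame())


class TestHarmonisation:
    def test_sort_oracle(self):
        cents = np.array([[3.1, 0.0], [0.5, 0.0], [1.7, 0.0]])
        maps = harmonize_labels([cents])
        np.testing.assert_array_equal(maps[0], [3, 1, 2])

    def test_identity_when_already_ascending(self):
        cents = np.array([[0.5, 0.0], [1.7, 0.0], [3.1, 0.0]])
        np.testing.assert_array_equal(harmonize_labels([cents])[0], [1, 2, 3])

    def test_descending_flag(self):
        cents = np.array([[0.5, 0.0], [1.7, 0.0], [3.1, 0.0]])
        np.testing.assert_array_equal(harmonize_labels([cents], ascending=False)[0],
                                      [3, 2, 1])

    def test_map_is_permutation(self, rng):
        for _ in range(10):
            cents = rng.normal(size=(4, 3))
            mp = harmonize_labels([cents])[0]
            assert sorted(mp) == [1, 2, 3, 4]

    def test_tied_norms_break_by_first_coordinate(self):
        cents = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 0.0]])
        mp = harmonize_labels([cents])[0]
        np.testing.assert_array_equal(mp, [3, 2, 1])

    def test_apply_harmonization(self):
        mp = np.array([3, 1, 2])
        np.testing.assert_array_equal(apply_harmonization(np.array([0, 1, 2, 0]), mp),
                                      [3, 1, 2, 3])

    def test_mismatched_k_rejected(self, rng):
        with pytest.raises(ClusteringError):
            harmonize_labels([rng.normal(size=(3, 2)), rng.normal(size=(4, 2))])
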