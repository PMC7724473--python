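"""Correlation-distance k-means, elbow selection, and the peak filters."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from pcs.cluster import (
    ClusterAssignment,
    CorrelationKMeans,
    build_feature_matrix,
    exclude_solo_peaks,
    kmeans_correlation,
    pearson_distance,
    relabel_clusters,
    select_k_elbow,
)
from pcs.coverage import SignalMatrix
from pcs.intervals import GenomicInterval, PeakSet


def test_pearson_distance_values():
    x = np.array([0.0, 1.0, 2.0])
    assert pearson_distance(x, x) == pytest.approx(0.0)
    assert pearson_distance(x, -x) == pytest.approx(2.0)
    d = pearson_distance([0, 1, 2], [0, 2, 3])
    assert d == pytest.approx(1 - 0.9819805, abs=1e-6)


def test_pearson_distance_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        pearson_distance([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="at least 3"):
        pearson_distance([1.0, 2.0], [3.0, 4.0])


def test_two_identical_groups_recovered_exactly():
    a, b = [1.0, 5.0, 2.0, 7.0], [4.0, 0.0, 6.0, 1.0]
    X = np.array([a] * 5 + [b] * 4)
    est = CorrelationKMeans(n_clusters=2, random_state=0).fit(X)
    assert est.inertia_ == pytest.approx(0.0, abs=1e-12)
    assert len(set(est.labels_[:5])) == 1
    assert len(set(est.labels_[5:])) == 1
    assert est.labels_[0] != est.labels_[-1]


def test_affine_invariance_of_assignment(rng):
    """Correlation distance ignores per-row offset and positive scale."""
    X = rng.normal(size=(30, 12))
    X[:15] += np.linspace(-2, 2, 12)  # two loose groups
    base = CorrelationKMeans(n_clusters=2, random_state=1).fit_predict(X)
    X2 = X.copy()
    X2[7] = 3.0 * X2[7] + 7.0
    moved = CorrelationKMeans(n_clusters=2, random_state=1).fit_predict(X2)
    assert adjusted_rand_score(base, moved) == 1.0


def _oracle_best_bipartition(X):
    """Exhaustive search over all bipartitions of the rows of X.

    The optimal centroid under summed Pearson distance is the normalized
    mean of the standardized rows (closed form), so each bipartition's
    objective is computable directly with scipy's pearsonr.
    """
    n = X.shape[0]
    Z = stats.zscore(X, axis=1, ddof=0)
    best = (np.inf, None)
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        total = 0.0
        for group in (mask, ~mask):
            centroid = Z[group].sum(axis=0)
            if np.ptp(centroid) == 0:
                total = np.inf
                break
            total += sum(1 - stats.pearsonr(X[i], centroid).statistic
                         for i in np.flatnonzero(group))
        if total < best[0]:
            best = (total, mask)
    return best


def test_kmeans_matches_exhaustive_bipartition_search(rng):
    """k=2 on six rows attains the optimum of the 31-bipartition search.

    Random-partition restarts can reach every Lloyd fixed point, including
    optima whose basin contains no point-pair seeding.
    """
    for _ in range(10):
        X = rng.normal(size=(6, 8))
        opt, _mask = _oracle_best_bipartition(X)
        est = CorrelationKMeans(n_clusters=2, n_init=300, random_state=0,
                                init="random-partition").fit(X)
        assert est.inertia_ == pytest.approx(opt, abs=1e-8)


def test_matches_zscore_euclidean_kmeans(rng):
    """Direct Pearson Lloyd agrees with z-score + Euclidean k-means.

    Row-wise z-scoring maps Pearson distance onto squared Euclidean
    distance (up to the monotone factor 2p), so both routes find the same
    partition on well-posed instances.
    """
    agreements = []
    for trial in range(20):
        t1, t2 = rng.normal(size=(2, 10))
        rows = [t1 + rng.normal(0, 0.4, 10) for _ in range(7)] + \
               [t2 + rng.normal(0, 0.4, 10) for _ in range(7)]
        X = np.array(rows)
        ours = CorrelationKMeans(n_clusters=2, n_init=10, random_state=trial).fit_predict(X)
        Z = stats.zscore(X, axis=1, ddof=0)
        ref = KMeans(n_clusters=2, n_init=10, random_state=trial).fit_predict(Z)
        agreements.append(adjusted_rand_score(ours, ref))
    assert all(a == 1.0 for a in agreements)


def test_inertia_non_increasing_in_k(rng):
    X = rng.normal(size=(40, 12))
    inertias = [CorrelationKMeans(n_clusters=k, n_init=5, random_state=0)
                .fit(X).inertia_ for k in range(2, 8)]
    assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))


def test_zero_variance_rows_flagged_not_crashing():
    a, b = [1.0, 5.0, 2.0, 7.0], [4.0, 0.0, 6.0, 1.0]
    X = np.array([a] * 4 + [b] * 4 + [[3.0, 3.0, 3.0, 3.0]])
    est = CorrelationKMeans(n_clusters=2, random_state=0).fit(X)
    assert list(est.zero_variance_rows_) == [8]
    assert est.labels_.shape == (9,)


def test_k_larger_than_distinct_rows_rejected():
    X = np.array([[1.0, 2.0, 3.0]] * 10)
    with pytest.raises(ValueError, match="distinct"):
        CorrelationKMeans(n_clusters=3, random_state=0).fit(X)


def test_elbow_recovers_three_planted_profiles(rng):
    """Three mutually anti-correlated templates give a knee at k = 3."""
    angles = [0.0, 2 * np.pi / 3, 4 * np.pi / 3]
    t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    templates = [np.cos(t + a) for a in angles]
    X = np.array([templates[i % 3] + rng.normal(0, 0.25, 24) for i in range(60)])
    res = select_k_elbow(X, 2, 8, seed=0)
    assert res.k == 3
    assert res.pronounced


def test_elbow_flags_pure_noise(rng):
    X = rng.normal(size=(60, 24))
    res = select_k_elbow(X, 2, 8, seed=0)
    assert not res.pronounced


def test_elbow_parameter_validation(rng):
    X = rng.normal(size=(10, 6))
    with pytest.raises(ValueError, match="k_min"):
        select_k_elbow(X, 1, 5)
    with pytest.raises(ValueError, match="k_max"):
        select_k_elbow(X, 3, 4)
    with pytest.raises(ValueError, match="fewer rows"):
        select_k_elbow(X, 2, 11)


def _assignment(labels, k, stats_dim=3):
    labels = np.asarray(labels)
    return ClusterAssignment(
        peak_ids=[f"p{i}" for i in range(labels.size)], labels=labels,
        centroids=np.zeros((k, stats_dim)), k=k, inertia=0.0, seed=0, n_init=1)


def test_relabel_clusters_orders_by_stat():
    a = _assignment([1, 1, 2, 2, 2, 3], k=3)
    ordered = relabel_clusters(a, np.array([5.0, 3.0, 1.0]))
    np.testing.assert_array_equal(ordered.labels, a.labels)  # identity
    reverse = relabel_clusters(a, np.array([1.0, 3.0, 5.0]))
    np.testing.assert_array_equal(reverse.labels, [3, 3, 2, 2, 2, 1])


def test_relabel_matches_independent_sort(rng):
    labels = rng.integers(1, 7, size=200)
    # force all six clusters present
    labels[:6] = np.arange(1, 7)
    a = _assignment(labels, k=6)
    stat = rng.normal(size=6)
    out = relabel_clusters(a, stat)
    ranks = {old + 1: rank + 1 for rank, old in
             enumerate(np.argsort(-stat, kind="stable"))}
    expected = np.array([ranks[int(c)] for c in labels])
    np.testing.assert_array_equal(out.labels, expected)


def test_relabel_tie_break_by_size_then_id():
    a = _assignment([1, 2, 2, 3], k=3)
    out = relabel_clusters(a, np.array([1.0, 1.0, 1.0]))
    # all stats tie: biggest cluster (2) first, then ids 1, 3
    np.testing.assert_array_equal(out.labels, [2, 1, 1, 3])


def _mat(values):
    values = np.asarray(values, float)
    return SignalMatrix(values, [f"p{i}" for i in range(values.shape[0])],
                        window_half_width=values.shape[1] * 25, bin_size=50)


def test_exclude_solo_peaks_counts():
    peaks = PeakSet([GenomicInterval("chr1", 100 * i, 100 * i + 50, name=f"p{i}")
                     for i in range(100)])
    companion = np.full((100, 4), 0.1)
    companion[:40] = 5.0  # exactly 40 enriched rows
    kept, mask = exclude_solo_peaks(peaks, [_mat(companion)], [1.0], min_marks=1)
    assert len(kept) == 40 and mask.sum() == 40
    ident, _ = exclude_solo_peaks(peaks, [_mat(companion)], [1.0], min_marks=0)
    assert len(ident) == 100


def test_exclude_solo_peaks_zero_signal_dropped():
    peaks = PeakSet([GenomicInterval("chr1", 0, 50, name="p0")])
    kept, _ = exclude_solo_peaks(peaks, [_mat(np.zeros((1, 4)))], [1.0], min_marks=1)
    assert len(kept) == 0


def test_cluster_assignment_requires_contiguous_labels():
    with pytest.raises(ValueError, match="contiguous"):
        _assignment([1, 3, 3], k=3)


def test_build_feature_matrix_blocks(rng):
    m1, m2 = _mat(rng.random((4, 8))), _mat(rng.random((4, 8)))
    X = build_feature_matrix([m1, m2])
    assert X.shape == (4, 16)
    np.testing.assert_array_equal(X[:, :8], m1.values)
    Z = build_feature_matrix([m1, m2], block_standardize=True)
    np.testing.assert_allclose(Z[:, :8].mean(axis=1), 0.0, atol=1e-12)
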