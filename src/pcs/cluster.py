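"""Stratification of the peak universe by multi-condition signal shape.

The stratification clusters peak-centered windows (±1 kb)
drawn from many ChIP conditions jointly, using Pearson correlation as the
distance between peaks: ``d(x, y) = 1 − r(x, y)``. Lloyd's algorithm under
this distance is equivalent to spherical k-means on row-centered,
L2-normalized vectors — for unit-norm centered rows,
``d(x, c) = (‖x̃ − c̃‖²) / 2`` whenever the centroid is renormalized, so the
assignment step under Euclidean and under Pearson distance coincide and
the objective differs only by the monotone map ``d ↦ 2d``.
:class:`CorrelationKMeans` implements this directly (centroid = normalized
mean direction of its members), which makes the optimized objective exactly
the summed Pearson distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from pcs.coverage import SignalMatrix, occupied_rows
from pcs.intervals import PeakSet


def pearson_distance(x, y) -> float:
    """Pearson correlation distance ``1 − r(x, y)``, in [0, 2].

    Raises for vectors shorter than 3 or with zero variance, for which the
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: Pearson distance undefined")
    return float(1.0 - stats.pearsonr(x, y).statistic)


def _center_normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-center and L2-normalize; returns (X_tilde, zero_variance_mask)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    return Xc / safe[:, None], degenerate


class CorrelationKMeans(ClusterMixin, BaseEstimator):
    """K-means under Pearson correlation distance.

    Lloyd iterations on row-centered, unit-norm vectors with centroid
    renormalization, so the objective minimized is exactly
    ``sum_i (1 − r(x_i, centroid_{label_i}))``. Deterministic for a fixed
    ``random_state``; the best of ``n_init`` seeded restarts is kept.

    Rows with zero variance (flat signal) have no defined correlation;
    they are excluded from centroid estimation, assigned afterwards by
    Euclidean distance between the raw row and the raw-space cluster
    means, and flagged in ``zero_variance_rows_``.

    Parameters
    ----------
    n_clusters:
        Number of clusters k (>= 2).
    n_init:
        Number of independent k-means++ style restarts.
    max_iter:
        Lloyd iteration cap per restart; non-convergence yields the best
        solution so far plus a warning and ``converged_ = False``.
    random_state:
        Seed for initialization (mandatory for reproducible pipelines).
    init:
        ``"kmeans++"`` (default) seeds centroids at data points with
        distance-proportional sampling; ``"random-partition"`` starts each
        restart from a uniformly random label assignment. Partition seeding
        explores fixed points that no point-pair seeding can reach, which
        matters for exhaustive-search comparisons on very small inputs.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster index in ``0..k-1`` per row.
    cluster_centers_ : ndarray of shape (k, p)
        Centered, unit-norm centroid directions.
    inertia_ : float
        Summed Pearson distance of non-degenerate rows to their centroid.
    """

    def __init__(self, n_clusters: int = 6, n_init: int = 10,
                 max_iter: int = 300, random_state: int | None = 0,
                 init: str = "kmeans++"):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.init = init

    # -- internals ---------------------------------------------------------

    def _init_centroids(self, Xt: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """k-means++ style seeding under Pearson distance."""
        n = Xt.shape[0]
        centers = np.empty((self.n_clusters, Xt.shape[1]))
        first = rng.integers(n)
        centers[0] = Xt[first]
        closest = 1.0 - Xt @ centers[0]
        np.maximum(closest, 0.0, out=closest)
        for j in range(1, self.n_clusters):
            total = closest.sum()
            if total <= 0:
                idx = rng.integers(n)
            else:
                idx = rng.choice(n, p=closest / total)
            centers[j] = Xt[idx]
            np.minimum(closest, 1.0 - Xt @ centers[j], out=closest)
            np.maximum(closest, 0.0, out=closest)
        return centers

    def _partition_centroids(self, Xt: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
        """Centroids of a uniformly random full partition of the rows."""
        n = Xt.shape[0]
        while True:
            labels = rng.integers(self.n_clusters, size=n)
            if np.unique(labels).size == self.n_clusters:
                break
        centers = np.empty((self.n_clusters, Xt.shape[1]))
        for j in range(self.n_clusters):
            direction = Xt[labels == j].sum(axis=0)
            norm = np.linalg.norm(direction)
            centers[j] = direction / norm if norm > 0 else Xt[rng.integers(n)]
        return centers

    def _lloyd(self, Xt: np.ndarray, centers: np.ndarray):
        n = Xt.shape[0]
        labels = np.full(n, -1)
        converged = False
        for _ in range(self.max_iter):
            # assignment: max correlation == min Pearson distance
            sims = Xt @ centers.T
            new_labels = np.argmax(sims, axis=1)
            if np.array_equal(new_labels, labels):
                converged = True
                break
            labels = new_labels
            dists = 1.0 - sims[np.arange(n), labels]
            for j in range(self.n_clusters):
                members = labels == j
                if not members.any():
                    # re-seed at the point farthest from its centroid
                    far = int(np.argmax(dists))
                    centers[j] = Xt[far]
                    labels[far] = j
                    dists[far] = 0.0
                    members = labels == j
                direction = Xt[members].sum(axis=0)
                norm = np.linalg.norm(direction)
                if norm > 0:
                    centers[j] = direction / norm
        sims = Xt @ centers.T
        labels = np.argmax(sims, axis=1)
        inertia = float(np.sum(1.0 - sims[np.arange(n), labels]))
        return labels, centers, inertia, converged

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (peaks x features)")
        n, p = X.shape
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if p < 3:
            raise ValueError("need at least 3 features for Pearson distance")
        Xt, degenerate = _center_normalize(X)
        n_distinct = np.unique(np.round(Xt[~degenerate], 12), axis=0).shape[0]
        if n_distinct < self.n_clusters:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the {n_distinct} "
                "distinct non-degenerate rows"
            )
        active = ~degenerate
        Xa = Xt[active]

        if self.init not in ("kmeans++", "random-partition"):
            raise ValueError(f"unknown init {self.init!r}")
        seed_seq = np.random.SeedSequence(self.random_state)
        best = None
        any_converged = False
        for child in seed_seq.spawn(self.n_init):
            rng = np.random.Generator(np.random.PCG64(child))
            if self.init == "kmeans++":
                centers = self._init_centroids(Xa, rng)
            else:
                centers = self._partition_centroids(Xa, rng)
            labels, centers, inertia, converged = self._lloyd(Xa, centers.copy())
            any_converged = any_converged or converged
            if best is None or inertia < best[2]:
                best = (labels, centers, inertia)
        labels_a, centers, inertia = best

        labels = np.empty(n, dtype=int)
        labels[active] = labels_a
        if degenerate.any():
            # raw-space means for the Euclidean fallback assignment
            raw_means = np.vstack([
                X[active][labels_a == j].mean(axis=0)
                for j in range(self.n_clusters)
            ])
            for i in np.flatnonzero(degenerate):
                labels[i] = int(np.argmin(np.linalg.norm(raw_means - X[i], axis=1)))
        if not any_converged:
            warnings.warn(
                "correlation k-means did not converge within max_iter in any "
                "restart; returning best solution so far",
                RuntimeWarning,
            )
        self.labels_ = labels
        self.cluster_centers_ = centers
        self.inertia_ = inertia
        self.converged_ = any_converged
        self.zero_variance_rows_ = np.flatnonzero(degenerate)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        Xt, degenerate = _center_normalize(X)
        if degenerate.any():
            raise ValueError("cannot predict zero-variance rows")
        return np.argmax(Xt @ self.cluster_centers_.T, axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def transform(self, X):
        """Pearson distances to each centroid."""
        check_is_fitted(self, "cluster_centers_")
        Xt, _ = _center_normalize(np.asarray(X, dtype=float))
        return 1.0 - Xt @ self.cluster_centers_.T


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) over an ordered peak universe."""

    peak_ids: list[str]
    labels: np.ndarray  # 1-based cluster ids, aligned with peak_ids
    centroids: np.ndarray  # k x features
    k: int
    inertia: float
    seed: int | None
    n_init: int
    zero_variance_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(
                f"cluster ids must be contiguous 1..{self.k} with no empty "
                f"cluster, got {present.tolist()}"
            )
        if len(self.peak_ids) != self.labels.size:
            raise ValueError("one label per peak required")

    def sizes(self) -> dict[int, int]:
        return {int(c): int((self.labels == c).sum()) for c in range(1, self.k + 1)}

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def kmeans_correlation(X: np.ndarray, peak_ids: list[str], k: int,
                       seed: int | None = 0, n_init: int = 10,
                       max_iter: int = 300) -> ClusterAssignment:
    """Functional wrapper: fit :class:`CorrelationKMeans`, return a
    1-based :class:`ClusterAssignment`."""
    est = CorrelationKMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                            random_state=seed).fit(X)
    return ClusterAssignment(
        peak_ids=list(peak_ids),
        labels=est.labels_ + 1,
        centroids=est.cluster_centers_,
        k=k,
        inertia=est.inertia_,
        seed=seed,
        n_init=n_init,
        zero_variance_rows=est.zero_variance_rows_,
        converged=est.converged_,
    )


@dataclass
class ElbowResult:
    """Outcome of elbow-based k selection on an inertia curve."""

    k: int
    ks: np.ndarray
    inertias: np.ndarray
    second_differences: np.ndarray  # aligned with ks[1:-1]
    pronounced: bool  # False when no knee exceeds the curvature tolerance


def select_k_elbow(X: np.ndarray, k_min: int = 2, k_max: int = 10,
                   seed: int | None = 0, n_init: int = 10,
                   curvature_tolerance: float = 0.5) -> ElbowResult:
    """Choose k at the knee of the inertia-vs-k curve.

    Fits :class:`CorrelationKMeans` for every k in ``[k_min, k_max]`` and
    returns the interior k maximizing the discrete second difference
    ``I(k−1) − 2 I(k) + I(k+1)``. A knee counts as pronounced only when
    that maximum curvature reaches ``curvature_tolerance`` times the
    largest single-step inertia drop of the curve; a smooth, steadily
    flattening curve (e.g. unstructured data) stays below this for any
    sizable tolerance, and the result is then flagged
    (``pronounced = False``) while still reporting the best k.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max <= k_min + 1:
        raise ValueError("k_max must exceed k_min + 1")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k_max:
        raise ValueError("fewer rows than k_max")
    ks = np.arange(k_min, k_max + 1)
    inertias = np.empty(ks.size)
    for i, k in enumerate(ks):
        est = CorrelationKMeans(n_clusters=int(k), n_init=n_init,
                                random_state=seed).fit(X)
        inertias[i] = est.inertia_
    d2 = inertias[:-2] - 2 * inertias[1:-1] + inertias[2:]
    best = int(np.argmax(d2))
    max_drop = float(np.max(inertias[:-1] - inertias[1:], initial=0.0))
    pronounced = bool(max_drop > 0
                      and d2[best] >= curvature_tolerance * max_drop)
    return ElbowResult(k=int(ks[1 + best]), ks=ks, inertias=inertias,
                       second_differences=d2, pronounced=pronounced)


def exclude_solo_peaks(ref_peaks: PeakSet,
                       companion_matrices: list[SignalMatrix],
                       background_means: list[float],
                       min_marks: int = 1,
                       enrichment_threshold: float = 2.0) -> tuple[PeakSet, np.ndarray]:
    """Drop peaks not supported by enough companion marks.

    A peak is retained when at least ``min_marks`` of the companion
    matrices show enrichment at its row (mean window signal above
    ``enrichment_threshold`` × that track's background mean). This is the
    filter that removes solo peaks of a single subunit — e.g. JARID2-only
    sites with little or no occupancy of the other PRC2 subunits — before
    building the common universe.

    Returns the filtered :class:`PeakSet` and the boolean keep-mask.
    """
    if len(companion_matrices) != len(background_means):
        raise ValueError("one background mean per companion matrix required")
    for m in companion_matrices:
        if m.n_peaks != len(ref_peaks):
            raise ValueError("companion matrix rows misaligned with peaks")
    if min_marks == 0 or not companion_matrices:
        keep = np.ones(len(ref_peaks), dtype=bool)
    else:
        support = np.zeros(len(ref_peaks), dtype=int)
        for m, bg in zip(companion_matrices, background_means):
            support += occupied_rows(m, bg, enrichment_threshold)
        keep = support >= min_marks
    return ref_peaks.subset(np.flatnonzero(keep)), keep


def relabel_clusters(assignment: ClusterAssignment,
                     ordering_stat: np.ndarray) -> ClusterAssignment:
    """Renumber clusters 1..k by descending ``ordering_stat``.

    ``ordering_stat[j]`` scores original cluster ``j+1`` (e.g. mean WT
    signal sharpness: center-bin over window-mean ratio). Ties break by
    larger cluster size, then by smaller original id, so the relabeling is
    always a bijection.
    """
    ordering_stat = np.asarray(ordering_stat, dtype=float)
    if ordering_stat.size != assignment.k:
        raise ValueError("need exactly one statistic per cluster")
    sizes = assignment.sizes()
    order = sorted(
        range(1, assignment.k + 1),
        key=lambda c: (-ordering_stat[c - 1], -sizes[c], c),
    )
    old_to_new = {old: new for new, old in enumerate(order, start=1)}
    new_labels = np.array([old_to_new[int(c)] for c in assignment.labels])
    perm = np.array([o - 1 for o in order])
    return ClusterAssignment(
        peak_ids=assignment.peak_ids,
        labels=new_labels,
        centroids=assignment.centroids[perm],
        k=assignment.k,
        inertia=assignment.inertia,
        seed=assignment.seed,
        n_init=assignment.n_init,
        zero_variance_rows=assignment.zero_variance_rows,
        converged=assignment.converged,
    )


def build_feature_matrix(matrices: list[SignalMatrix],
                         block_standardize: bool = False) -> np.ndarray:
    """Concatenate per-condition peak windows into the clustering features.

    By default condition blocks are concatenated as they are: the single
    row-wise centering/scaling implicit in the Pearson distance then
    preserves relative amplitudes *between* conditions, which is where the
    per-condition residual structure lives (a broad domain has no
    within-window shape, only a level). Setting ``block_standardize`` to
    True z-scores each condition block per row first, restricting the
    distance to within-window shape only.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    ids = matrices[0].peak_ids
    for m in matrices[1:]:
        if m.peak_ids != ids:
            raise ValueError("matrices cover different peak universes")
    blocks = []
    for m in matrices:
        v = m.values
        if block_standardize:
            mu = v.mean(axis=1, keepdims=True)
            sd = v.std(axis=1, keepdims=True)
            sd = np.where(sd == 0, 1.0, sd)
            v = (v - mu) / sd
        blocks.append(v)
    return np.hstack(blocks)
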