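"""Stage 2: cluster analysis of the cohort profile matrix.

Four algorithms are provided — k-means (Lloyd with k-means++ restarts),
normalized spectral clustering, DBSCAN and Ward agglomerative — together
with elbow-based selection of the number of clusters from the k-means
inertia curve and the adjusted Rand index for comparing partitions.

All algorithms are implemented here from first principles so their
behaviour (initialisation, tie-breaking, stopping rules) is fully
specified; the test suite cross-checks them against scikit-learn on
fixed fixtures.  Every stochastic routine takes an explicit integer seed
and is deterministic given it.

The elbow rule is formalised as the maximal second forward difference of
the inertia curve: k* = argmax_{2<=k<=kmax-1} (I(k-1)-I(k)) - (I(k)-I(k+1)),
ties broken toward smaller k.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .profiling import ProfileMatrix

__all__ = [
    "ClusterResult",
    "InertiaCurve",
    "kmeans",
    "inertia_curve",
    "select_k_elbow",
    "spectral",
    "dbscan",
    "agglomerative",
    "adjusted_rand_index",
    "cluster_sizes",
]

_ALGORITHMS = ("spectral", "kmeans", "dbscan", "agglomerative")


@dataclass
class ClusterResult:
    """Labels from one algorithm at one k (k is None for DBSCAN)."""

    algorithm: str
    labels: np.ndarray
    k: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D vector")
        if self.algorithm != "dbscan":
            if self.k is None:
                raise ValueError("k required for non-DBSCAN results")
            present = set(self.labels.tolist())
            if present != set(range(self.k)):
                raise ValueError(
                    f"labels must cover 0..{self.k - 1} with no empty cluster"
                )
        elif np.any(self.labels < -1):
            raise ValueError("DBSCAN labels must be >= -1")

    @property
    def n_samples(self) -> int:
        return int(self.labels.size)


@dataclass
class InertiaCurve:
    """k-means inertia for k = 1..k_max (best over restarts)."""

    k_values: np.ndarray
    inertias: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=np.int64)
        self.inertias = np.asarray(self.inertias, dtype=np.float64)
        if self.k_values.shape != self.inertias.shape:
            raise ValueError("k_values and inertias must align")
        if not np.array_equal(
            self.k_values, np.arange(1, self.k_values.size + 1)
        ):
            raise ValueError("k_values must be 1..k_max")
        drops = np.diff(self.inertias)
        if np.any(drops > 1e-9 * max(self.inertias[0], 1.0)):
            raise ValueError("inertia must be non-increasing in k")

    @property
    def k_max(self) -> int:
        return int(self.k_values[-1])


def _as_array(matrix: ProfileMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ProfileMatrix):
        return matrix.values
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return x


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

_MAX_ITER = 300


def _kmeanspp_init(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding: D^2-weighted sampling of initial centers."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            idx = rng.choice(n, p=d2 / total)
        else:  # all remaining distances zero: duplicate points
            idx = rng.integers(n)
        centers[j] = x[idx]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    x: np.ndarray, centers: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations until assignments stabilise (or 300 iterations).

    Empty clusters are re-seeded with the point farthest from its center
    so every cluster stays non-empty.
    """
    n, k = x.shape[0], centers.shape[0]
    labels = np.full(n, -1)
    for _ in range(_MAX_ITER):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for j in range(k):
            if not np.any(new_labels == j):
                farthest = int(d2[np.arange(n), new_labels].argmax())
                new_labels[farthest] = j
                centers[j] = x[farthest]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = x[labels == j].mean(axis=0)
    inertia = float(((x - centers[labels]) ** 2).sum())
    return labels, centers, inertia


def _kmeans_best(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_restarts: int,
    warm_centers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    inits = [_kmeanspp_init(x, k, rng) for _ in range(n_restarts)]
    if warm_centers is not None:
        inits.append(warm_centers)
    for init in inits:
        labels, centers, inertia = _lloyd(x, init.copy())
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    assert best is not None
    return best


def kmeans(
    matrix: ProfileMatrix | np.ndarray,
    k: int,
    seed: int,
    n_restarts: int = 10,
) -> tuple[ClusterResult, float]:
    """Best-of-restarts k-means; returns the partition and its inertia."""
    x = _as_array(matrix)
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k={k} out of range for {x.shape[0]} samples")
    rng = np.random.default_rng(seed)
    labels, _, inertia = _kmeans_best(x, k, rng, n_restarts)
    return (
        ClusterResult(algorithm="kmeans", labels=labels, k=k, seed=seed),
        inertia,
    )


def inertia_curve(
    matrix: ProfileMatrix | np.ndarray,
    k_max: int,
    seed: int,
    n_restarts: int = 10,
) -> InertiaCurve:
    """k-means inertia for each k in 1..k_max.

    In addition to the k-means++ restarts, each k is warm-started from
    the previous k's best centers plus the point farthest from its
    center, which guarantees the curve is non-increasing.
    """
    x = _as_array(matrix)
    if not 1 <= k_max <= x.shape[0]:
        raise ValueError(f"k_max={k_max} out of range")
    inertias = []
    prev_centers: np.ndarray | None = None
    prev_labels: np.ndarray | None = None
    for k in range(1, k_max + 1):
        rng = np.random.default_rng([seed, k])
        warm = None
        if prev_centers is not None:
            resid = ((x - prev_centers[prev_labels]) ** 2).sum(axis=1)
            warm = np.vstack([prev_centers, x[int(resid.argmax())]])
        labels, centers, inertia = _kmeans_best(x, k, rng, n_restarts, warm)
        inertias.append(inertia)
        prev_centers, prev_labels = centers, labels
    return InertiaCurve(np.arange(1, k_max + 1), np.asarray(inertias))


def select_k_elbow(curve: InertiaCurve) -> int:
    """Elbow rule: k with the maximal second forward difference.

    d(k) = (I(k-1) - I(k)) - (I(k) - I(k+1)) over k = 2..k_max-1;
    ties break toward the smaller k.
    """
    if curve.k_max < 3:
        raise ValueError("need k_max >= 3 for elbow selection")
    inertia = curve.inertias
    d = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
    return int(np.argmax(d)) + 2


# ---------------------------------------------------------------------------
# Spectral clustering
# ---------------------------------------------------------------------------


def spectral(
    matrix: ProfileMatrix | np.ndarray, k: int, seed: int
) -> ClusterResult:
    """Normalized spectral clustering (RBF affinity, symmetric Laplacian).

    The affinity is A_ij = exp(-gamma * ||x_i - x_j||^2) with the median
    heuristic gamma = 1 / (2 * median pairwise squared distance); the k
    eigenvectors of the smallest eigenvalues of
    L = I - D^{-1/2} A D^{-1/2} are row-normalized and clustered with
    k-means.
    """
    x = _as_array(matrix)
    n = x.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    d2_condensed = pdist(x, metric="sqeuclidean")
    median = float(np.median(d2_condensed))
    if median == 0.0:
        positive = d2_condensed[d2_condensed > 0]
        if positive.size == 0:
            raise ValueError("degenerate affinity: all points are identical")
        median = float(np.median(positive))
    gamma = 1.0 / (2.0 * median)
    affinity = np.exp(-gamma * squareform(d2_condensed))
    degree = affinity.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degree)
    laplacian = np.eye(n) - inv_sqrt[:, None] * affinity * inv_sqrt[None, :]
    laplacian = 0.5 * (laplacian + laplacian.T)  # symmetrise fp error
    _, vectors = eigh(laplacian, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vectors, axis=1)
    norms[norms == 0] = 1.0
    embedding = vectors / norms[:, None]
    result, _ = kmeans(embedding, k, seed)
    return ClusterResult(
        algorithm="spectral", labels=result.labels, k=k, seed=seed
    )


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------


def dbscan(
    matrix: ProfileMatrix | np.ndarray, eps: float, min_samples: int
) -> ClusterResult:
    """Density-based clustering; -1 marks noise.

    Core points have at least ``min_samples`` neighbours within ``eps``
    (self included); clusters grow by density reachability; border
    points join the first core cluster that discovers them.  Iteration
    follows row order, so the result is deterministic.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    x = _as_array(matrix)
    n = x.shape[0]
    dist = squareform(pdist(x))
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([nb.size >= min_samples for nb in neighbors])
    labels = np.full(n, -1, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    cluster = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        visited[i] = True
        labels[i] = cluster
        queue = deque([i])
        while queue:
            j = queue.popleft()
            for nb in neighbors[j]:
                if labels[nb] == -1:
                    labels[nb] = cluster
                if core[nb] and not visited[nb]:
                    visited[nb] = True
                    queue.append(nb)
        cluster += 1
    return ClusterResult(algorithm="dbscan", labels=labels)


def median_knn_eps(matrix: ProfileMatrix | np.ndarray, k: int = 3) -> float:
    """Median distance to the k-th nearest neighbour — a default DBSCAN eps."""
    x = _as_array(matrix)
    dist = squareform(pdist(x))
    dist_sorted = np.sort(dist, axis=1)
    return float(np.median(dist_sorted[:, min(k, x.shape[0] - 1)]))


# ---------------------------------------------------------------------------
# Agglomerative (Ward)
# ---------------------------------------------------------------------------


def agglomerative(matrix: ProfileMatrix | np.ndarray, k: int) -> ClusterResult:
    """Bottom-up merging under Ward's criterion until k clusters remain.

    The pair minimising the Ward cost |A||B|/(|A|+|B|) * ||c_A - c_B||^2
    is merged at each step; ties break on the smallest pair of cluster
    indices (clusters keep the smaller member's index when merged).
    """
    x = _as_array(matrix)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    centroids: dict[int, np.ndarray] = {i: x[i].copy() for i in range(n)}
    while len(members) > k:
        keys = sorted(members)
        best_cost, best_pair = np.inf, None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                na, nb = len(members[a]), len(members[b])
                diff = centroids[a] - centroids[b]
                cost = na * nb / (na + nb) * float(diff @ diff)
                if cost < best_cost:
                    best_cost, best_pair = cost, (a, b)
        a, b = best_pair
        na, nb = len(members[a]), len(members[b])
        centroids[a] = (na * centroids[a] + nb * centroids[b]) / (na + nb)
        members[a].extend(members[b])
        del members[b], centroids[b]
    labels = np.empty(n, dtype=np.int64)
    for label, key in enumerate(sorted(members)):
        labels[members[key]] = label
    return ClusterResult(algorithm="agglomerative", labels=labels, k=k)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two samples")

    def comb2(v: np.ndarray) -> float:
        return float((v * (v - 1) / 2).sum())

    _, a_idx = np.unique(a, return_inverse=True)
    _, b_idx = np.unique(b, return_inverse=True)
    contingency = np.zeros((a_idx.max() + 1, b_idx.max() + 1))
    np.add.at(contingency, (a_idx, b_idx), 1)
    sum_cells = comb2(contingency.ravel())
    sum_a = comb2(contingency.sum(axis=1))
    sum_b = comb2(contingency.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def cluster_sizes(result: ClusterResult) -> tuple[np.ndarray, int]:
    """Cluster sizes in label order, plus the DBSCAN noise count."""
    labels = result.labels
    n_noise = int(np.sum(labels == -1))
    clustered = labels[labels >= 0]
    if clustered.size == 0:
        return np.empty(0, dtype=np.int64), n_noise
    sizes = np.bincount(clustered)
    return sizes.astype(np.int64), n_noise
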