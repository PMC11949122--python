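"""K-medoids (PAM) partitioning on precomputed distance matrices.

The clustering pipeline is: PAM BUILD (greedy medoid initialization)
followed by SWAP passes until no single medoid/non-medoid exchange strictly
reduces the total distance-to-medoid cost.  All ties (equal-cost swaps,
equidistant medoids) break toward the lowest index, so runs are fully
deterministic; the ``seed`` field exists for API symmetry and optional
random initialization.

``select_k`` scans k over a range (default 2-10) and keeps the solution
with the largest average silhouette width, ties toward smaller k.
Silhouette widths and the Adjusted Rand Index come from scikit-learn
(singleton clusters contribute silhouette 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .dtw import DistanceMatrix

__all__ = ["ClusterSolution", "k_medoids", "silhouette", "select_k",
           "adjusted_rand_index"]


@dataclass
class ClusterSolution:
    """A k-medoids partition of a distance matrix."""

    ids: list[str]
    labels: np.ndarray          # cluster index per patient, 1..k
    medoids: np.ndarray         # k point indices, ascending
    k: int
    avg_silhouette: float
    seed: int | None = None
    total_cost: float = float("nan")
    sil_trace: dict = field(default_factory=dict)  # k -> avg silhouette (select_k)

    def medoid_ids(self) -> list[str]:
        return [self.ids[m] for m in self.medoids]


@njit(cache=True)
def _pam_build(D, k):  # pragma: no cover - exercised via k_medoids
    n = D.shape[0]
    medoids = np.empty(k, np.int64)
    best, best_cost = 0, np.inf
    for i in range(n):
        c = 0.0
        for j in range(n):
            c += D[i, j]
        if c < best_cost:
            best_cost = c
            best = i
    medoids[0] = best
    dnear = D[best].copy()
    chosen = np.zeros(n, np.bool_)
    chosen[best] = True
    for m in range(1, k):
        best, best_gain = -1, -np.inf
        for c in range(n):
            if chosen[c]:
                continue
            gain = 0.0
            for j in range(n):
                diff = dnear[j] - D[c, j]
                if diff > 0.0:
                    gain += diff
            if gain > best_gain:
                best_gain = gain
                best = c
        medoids[m] = best
        chosen[best] = True
        for j in range(n):
            if D[best, j] < dnear[j]:
                dnear[j] = D[best, j]
    return np.sort(medoids)


@njit(cache=True)
def _pam_swap(D, medoids):  # pragma: no cover
    n = D.shape[0]
    k = len(medoids)
    medoids = medoids.copy()
    is_medoid = np.zeros(n, np.bool_)
    for m in medoids:
        is_medoid[m] = True
    nearest = np.empty(n, np.int64)    # position in medoid array
    dnear = np.empty(n)
    dsecond = np.empty(n)
    while True:
        for j in range(n):
            b1, b2, pos = np.inf, np.inf, 0
            for mi in range(k):
                d = D[medoids[mi], j]
                if d < b1:
                    b2 = b1
                    b1 = d
                    pos = mi
                elif d < b2:
                    b2 = d
            nearest[j] = pos
            dnear[j] = b1
            dsecond[j] = b2
        best_delta = -1e-12
        best_mi, best_h = -1, -1
        for mi in range(k):
            for h in range(n):
                if is_medoid[h]:
                    continue
                delta = 0.0
                for j in range(n):
                    dhj = D[h, j]
                    if nearest[j] == mi:
                        alt = dsecond[j]
                        if dhj < alt:
                            alt = dhj
                        delta += alt - dnear[j]
                    elif dhj < dnear[j]:
                        delta += dhj - dnear[j]
                if delta < best_delta:
                    best_delta = delta
                    best_mi, best_h = mi, h
        if best_mi < 0:
            break
        is_medoid[medoids[best_mi]] = False
        is_medoid[best_h] = True
        medoids[best_mi] = best_h
    return np.sort(medoids)


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    # nearest medoid; ties toward the lowest medoid index (argmin convention)
    dist_to_medoids = D[medoids][:, :]  # k x n
    pos = np.argmin(dist_to_medoids, axis=0)
    cost = float(dist_to_medoids[pos, np.arange(D.shape[0])].sum())
    return pos + 1, cost  # labels 1..k ordered by ascending medoid index


def k_medoids(dist: DistanceMatrix, k: int, seed: int | None = None,
              init: str = "build") -> ClusterSolution:
    """Partition points around k medoids with PAM BUILD + SWAP.

    Parameters
    ----------
    dist : DistanceMatrix
    k : int
        Number of clusters, ``2 <= k < n``.
    seed : int, optional
        Used only with ``init="random"``; the default BUILD initialization
        is deterministic.
    """
    n = dist.n
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    D = dist.values
    if init == "build":
        medoids = _pam_build(D, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        medoids = np.sort(rng.choice(n, size=k, replace=False))
    else:
        raise ValueError(f"unknown init {init!r}")
    medoids = _pam_swap(D, medoids.astype(np.int64))
    labels, cost = _assign(D, medoids)
    sil = silhouette(dist, labels)[1] if len(np.unique(labels)) > 1 else float("nan")
    return ClusterSolution(ids=dist.ids, labels=labels, medoids=medoids, k=k,
                           avg_silhouette=sil, seed=seed, total_cost=cost)


def silhouette(dist: DistanceMatrix, labels) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths and their mean for a labeling.

    ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` with a = mean within-cluster
    distance (self excluded) and b = smallest mean distance to another
    cluster; singleton clusters contribute 0.  Rejects a single-cluster
    labeling.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    widths = silhouette_samples(dist.values, labels, metric="precomputed")
    return widths, float(widths.mean())


def select_k(dist: DistanceMatrix, k_min: int = 2, k_max: int = 10,
             seed: int | None = None) -> ClusterSolution:
    """Run k-medoids across k in [k_min, k_max]; keep the max-silhouette fit.

    Ties break toward smaller k.  The silhouette trace for every k tried is
    retained on the returned solution (``sil_trace``).
    """
    if k_max >= dist.n:
        k_max = dist.n - 1
    if k_min > k_max:
        raise ValueError("empty k range")
    best = None
    trace = {}
    for k in range(k_min, k_max + 1):
        sol = k_medoids(dist, k, seed=seed)
        trace[k] = sol.avg_silhouette
        if best is None or sol.avg_silhouette > best.avg_silhouette:
            best = sol
    best.sil_trace = trace
    return best


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    1 for identical partitions (up to label renaming), expectation 0 for
    independent random labelings.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least 2 points")
    return float(adjusted_rand_score(labels_a, labels_b))
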