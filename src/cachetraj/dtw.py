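"""Normalized dynamic time warping over ordinal severity sequences.

The local cost between elements is the absolute difference of the ordinal
severity values.  The cumulative cost follows the classic three-direction
recursion (lateral, vertical, diagonal), with out-of-range predecessors
treated as +inf, and the terminal cumulative cost is normalized by the sum
of the two sequence lengths so longer sequences do not dominate::

    D(1,1) = d(1,1)
    D(i,j) = d(i,j) + min(D(i-1,j), D(i,j-1), D(i-1,j-1))
    dtw(a,b) = D(n,m) / (n + m)

Only the category values enter the alignment; measurement timestamps are
deliberately ignored (the alignment compares trajectory shapes, not
calendars).  No warping-window constraint is applied.

A null distance — the absolute difference in sequence lengths — is provided
for the measurement-intensity null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import squareform

from .scoring import SeveritySequence

__all__ = ["DistanceMatrix", "dtw_distance", "pairwise_matrix", "null_matrix",
           "write_distance_matrix", "read_distance_matrix"]


@njit(cache=True)
def _dtw_core(a, b):  # pragma: no cover - exercised via dtw_distance
    n, m = len(a), len(b)
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        c = abs(a[0] - b[j])
        prev[j] = c if j == 0 else c + prev[j - 1]
    for i in range(1, n):
        cur[0] = abs(a[i] - b[0]) + prev[0]
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = abs(a[i] - b[j]) + best
        prev, cur = cur, prev
    return prev[m - 1] / (n + m)


@njit(cache=True)
def _pairwise_core(flat, offsets):  # pragma: no cover
    n = len(offsets) - 1
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        a = flat[offsets[i]:offsets[i + 1]]
        for j in range(i + 1, n):
            out[idx] = _dtw_core(a, flat[offsets[j]:offsets[j + 1]])
            idx += 1
    return out


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative patient-by-patient distance matrix.

    Stored condensed (upper triangle, scipy ``squareform`` order) to halve
    memory; ``values`` materializes (and caches) the dense square view.
    """

    ids: list[str]
    condensed: np.ndarray
    kind: str  # "dtw_normalized" or "null_length"
    _dense: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.ids)
        expected = n * (n - 1) // 2
        self.condensed = np.asarray(self.condensed, dtype=float)
        if self.condensed.shape != (expected,):
            raise ValueError(f"condensed length {self.condensed.shape} does not "
                             f"match {n} ids")
        if np.any(self.condensed < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def values(self) -> np.ndarray:
        """Dense symmetric matrix with zero diagonal."""
        if self._dense is None:
            self._dense = squareform(self.condensed, checks=False)
        return self._dense


def dtw_distance(a, b) -> float:
    """Length-normalized DTW distance between two ordinal sequences.

    Accepts raw value arrays or :class:`SeveritySequence` objects.  Raises
    ``ValueError`` on an empty sequence.
    """
    if isinstance(a, SeveritySequence):
        a = a.values
    if isinstance(b, SeveritySequence):
        b = b.values
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    return float(_dtw_core(a, b))


def _check_eligible(sequences: list[SeveritySequence], min_len: int) -> None:
    bad = [s.patient_id for s in sequences if len(s) < min_len]
    if bad:
        raise ValueError(
            f"{len(bad)} sequence(s) shorter than {min_len} are ineligible: "
            + ", ".join(str(b) for b in bad[:20])
            + ("..." if len(bad) > 20 else ""))


def pairwise_matrix(sequences: list[SeveritySequence]) -> DistanceMatrix:
    """All-pairs normalized DTW distance matrix (each unordered pair once)."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    _check_eligible(sequences, min_len=2)
    flat = np.concatenate([s.values.astype(float) for s in sequences])
    offsets = np.zeros(len(sequences) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in sequences], out=offsets[1:])
    condensed = _pairwise_core(flat, offsets)
    return DistanceMatrix([s.patient_id for s in sequences], condensed,
                          "dtw_normalized")


def null_matrix(sequences: list[SeveritySequence]) -> DistanceMatrix:
    """Null distance matrix: absolute difference of measurement counts."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = np.array([len(s) for s in sequences], dtype=float)
    dense = np.abs(lengths[:, None] - lengths[None, :])
    return DistanceMatrix([s.patient_id for s in sequences],
                          squareform(dense, checks=False), "null_length")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Write a square delimited matrix with an id header row and column."""
    with open(path, "w") as fh:
        fh.write("id," + ",".join(str(i) for i in dm.ids) + "\n")
        fh.write(f"#kind={dm.kind}\n")
        dense = dm.values
        for i, pid in enumerate(dm.ids):
            fh.write(str(pid) + "," +
                     ",".join(format(v, ".17g") for v in dense[i]) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
        kind_line = fh.readline().strip()
        kind = kind_line.split("=", 1)[1] if "=" in kind_line else "dtw_normalized"
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split(",")
            rows.append([float(x) for x in parts[1:]])
    dense = np.asarray(rows, dtype=float)
    dense = 0.5 * (dense + dense.T)  # guard against asymmetric rounding
    np.fill_diagonal(dense, 0.0)
    return DistanceMatrix(header, squareform(dense, checks=False), kind)
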