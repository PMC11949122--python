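"""Independent oracles used by the tests.

These deliberately avoid the implementation's code paths: the DTW oracle is
a memoization-free recursive evaluation of the alignment recursion, and the
k-medoids oracle exhaustively enumerates medoid subsets.
"""

from itertools import combinations, product

import numpy as np


def dtw_naive(a, b) -> float:
    """Plain recursive DTW with (n+m) normalization; exponential time."""
    a = list(a)
    b = list(b)

    def rec(i, j):
        if i < 0 or j < 0:
            return float("inf")
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        return cost + min(rec(i - 1, j), rec(i, j - 1), rec(i - 1, j - 1))

    return rec(len(a) - 1, len(b) - 1) / (len(a) + len(b))


def all_sequences(lengths=(2, 3, 4, 5), alphabet=(0, 1, 2)):
    """Every ordinal sequence over the alphabet with the given lengths."""
    out = []
    for n in lengths:
        out.extend(list(p) for p in product(alphabet, repeat=n))
    return out


def best_medoids_exhaustive(D: np.ndarray, k: int):
    """Globally optimal medoid set by enumeration (tiny n only).

    Returns (medoids, cost); ties resolved toward the lexicographically
    smallest medoid tuple, matching the implementation's lowest-index rule.
    """
    n = D.shape[0]
    best, best_cost = None, np.inf
    for med in combinations(range(n), k):
        cost = D[list(med)].min(axis=0).sum()
        if cost < best_cost - 1e-12:
            best, best_cost = med, cost
    return np.array(best), float(best_cost)


def plain_concordance(times, events, marker, horizon) -> float:
    """Unweighted case/control concordance at a horizon (tie credit 1/2)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    marker = np.asarray(marker, float)
    cases = (times <= horizon) & (events == 1)
    ctrls = times > horizon
    num = 0.0
    for mi in marker[cases]:
        for mj in marker[ctrls]:
            num += 1.0 if mi > mj else (0.5 if mi == mj else 0.0)
    return num / (cases.sum() * ctrls.sum())
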