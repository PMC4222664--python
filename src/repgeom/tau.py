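"""Kendall tau-a rank correlation.

tau-a is the proportion of pairs of observations that are consistently
ordered in both variables, with the all-pairs denominator m(m-1)/2: tied
pairs count as neither concordant nor discordant and are *not* removed
from the denominator. This makes tau-a the right statistic when one of the
two dissimilarity vectors predicts tied ranks (e.g. a category-cluster
RDM): a candidate that predicts ties for genuinely different
dissimilarities is penalized rather than forgiven.

The pair counting uses Knight's O(m log m) algorithm: sort by the first
variable (ties broken by the second), count discordances as merge-sort
inversions of the second variable, and correct for ties via tie-group
counts. A brute-force O(m^2) enumeration exists in the test suite as an
independent oracle.
"""

from __future__ import annotations

import numpy as np

from .rdm import DissimilarityVector


def _merge_count(y: np.ndarray) -> int:
    """Number of inversions in y, counted by a vectorized merge sort."""
    n = y.size
    inv = 0
    width = 1
    y = y.copy()
    buf = np.empty_like(y)
    while width < n:
        for lo in range(0, n, 2 * width):
            mid = min(lo + width, n)
            hi = min(lo + 2 * width, n)
            if mid >= hi:
                buf[lo:hi] = y[lo:hi]
                continue
            left, right = y[lo:mid], y[mid:hi]
            # each right element is inverted with every strictly greater left element
            pos = np.searchsorted(left, right, side="right")
            inv += int((left.size - pos).sum())
            merged = np.concatenate([left, right])
            merged.sort(kind="stable")
            buf[lo:hi] = merged
        y, buf = buf, y
        width *= 2
    return inv


def _tie_count(sorted_vals: np.ndarray) -> int:
    """Sum over tie groups of t*(t-1)/2 for a sorted array."""
    _, counts = np.unique(sorted_vals, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def kendall_tau_a(x, y) -> float:
    """tau_A = (concordant - discordant) / (m(m-1)/2) over jointly valid entries.

    Accepts plain arrays or :class:`~repgeom.rdm.DissimilarityVector` pairs
    aligned on the same pair list; masked entries in either vector are
    excluded before counting.
    """
    x, y = _joint_valid(x, y)
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 jointly valid entries")
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    n0 = m * (m - 1) // 2
    n1 = _tie_count(xs)          # ties in x
    n2 = _tie_count(np.sort(y))  # ties in y
    # joint ties
    joint = np.empty(m, dtype=[("x", float), ("y", float)])
    joint["x"], joint["y"] = xs, ys
    _, counts = np.unique(joint, return_counts=True)
    n3 = int((counts * (counts - 1) // 2).sum())
    swaps = _merge_count(ys)
    c_minus_d = n0 - n1 - n2 + n3 - 2 * swaps
    return c_minus_d / n0


def _joint_valid(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, DissimilarityVector) and isinstance(y, DissimilarityVector):
        if len(x) != len(y):
            raise ValueError("dissimilarity vectors must share the pair list")
        both = x.mask & y.mask
        return x.values[both], y.values[both]
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("inputs must have equal length")
    both = np.isfinite(xa) & np.isfinite(ya)
    return xa[both], ya[both]


def tau_a_against_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """tau_A of a fixed vector ``x`` against each row of ``Y``.

    Vectorized over rows via the sign-matrix formulation
    C - D = sum_{a<b} sgn(x_a - x_b) * sgn(y_a - y_b); intended for the
    moderate vector lengths of permutation nulls (memory is O(rows * m^2)
    per chunk). Rows and ``x`` must be fully valid.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m = x.size
    n0 = m * (m - 1) // 2
    iu, ju = np.triu_indices(m, k=1)
    sx = np.sign(x[iu] - x[ju])
    out = np.empty(Y.shape[0])
    chunk = max(1, int(2_000_000 // max(1, iu.size)))
    for s in range(0, Y.shape[0], chunk):
        block = Y[s : s + chunk]
        sy = np.sign(block[:, iu] - block[:, ju])
        out[s : s + chunk] = sy @ sx / n0
    return out
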