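"""Compiled inner loops for the circular maximal-t scan.

The scan is an exhaustive O(N^2) evaluation of the two-sample t-like
statistic over every arc (i, j] of the circularized probe sequence.  The
complementary arc gives the negated statistic, so scanning contiguous arcs
covers the full circle.  These loops dominate the cost of permutation
testing and of building the null lookup tables, hence numba.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def scan_max_abs_t(prefix: np.ndarray, n: int, s: float, min_width: int):
    """Return (t_signed, i, j) maximizing |T_ij| over arcs with both arms
    >= min_width probes.

    ``prefix`` is the length-(n+1) prefix-sum array with prefix[0] = 0; ``s``
    the sample standard deviation of the full series.  Ties break to the
    lexicographically smallest (i, j).
    """
    total = prefix[n]
    best_abs = -1.0
    best_t = 0.0
    best_i = 0
    best_j = 0
    for k in range(min_width, n - min_width + 1):
        inv_k = 1.0 / k
        inv_rest = 1.0 / (n - k)
        denom = s * np.sqrt(inv_k + inv_rest)
        for i in range(0, n - k + 1):
            sij = prefix[i + k] - prefix[i]
            t = (sij * inv_k - (total - sij) * inv_rest) / denom
            a = abs(t)
            if a > best_abs:
                best_abs = a
                best_t = t
                best_i = i
                best_j = i + k
            elif a == best_abs:
                j = i + k
                if i < best_i or (i == best_i and j < best_j):
                    best_t = t
                    best_i = i
                    best_j = j
    return best_t, best_i, best_j


@numba.njit(cache=True)
def _max_abs_t_values(values: np.ndarray, min_width: int) -> float:
    """max |T_ij| of one series (recomputes prefix sums and sd)."""
    n = values.shape[0]
    mean = 0.0
    for v in values:
        mean += v
    mean /= n
    ss = 0.0
    for v in values:
        d = v - mean
        ss += d * d
    s = np.sqrt(ss / (n - 1))
    if s == 0.0:
        return 0.0
    prefix = np.empty(n + 1, dtype=np.float64)
    prefix[0] = 0.0
    acc = 0.0
    for idx in range(n):
        acc += values[idx]
        prefix[idx + 1] = acc
    t, _, _ = scan_max_abs_t(prefix, n, s, min_width)
    return abs(t)


@numba.njit(cache=True)
def batch_max_abs_t(matrix: np.ndarray, min_width: int) -> np.ndarray:
    """max |T_ij| per row of ``matrix`` (replicates x probes)."""
    out = np.empty(matrix.shape[0], dtype=np.float64)
    for r in range(matrix.shape[0]):
        out[r] = _max_abs_t_values(matrix[r], min_width)
    return out


@numba.njit(cache=True)
def permutation_exceedances(
    perm_matrix: np.ndarray,
    t_obs_abs: float,
    min_width: int,
    stop_count: int,
):
    """Count permutations whose max |T| >= t_obs_abs.

    Rows of ``perm_matrix`` are pre-generated permutations of the observed
    series.  Stops once the count reaches ``stop_count`` (pass a value larger
    than the row count to disable early stopping).  Returns
    (exceedances, permutations_examined).
    """
    exceed = 0
    done = 0
    for r in range(perm_matrix.shape[0]):
        tmax = _max_abs_t_values(perm_matrix[r], min_width)
        done += 1
        if tmax >= t_obs_abs:
            exceed += 1
            if exceed >= stop_count:
                break
    return exceed, done
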