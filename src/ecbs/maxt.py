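"""Circular maximal-t statistic and exhaustive arc scan.

For log2 ratios r_1..r_N with partial sums S_i, the statistic of the arc
(i, j] (k = j - i probes) against its complement is

    T_ij = (S_ij/k - (S_N - S_ij)/(N - k)) / (s * sqrt(1/k + 1/(N - k))),

with s the (n-1)-denominator sample standard deviation of the whole series.
The two ends of the sequence are conceptually joined into a circle: the
complement of a contiguous arc is the wrapped arc, and swapping the two
negates T, so scanning contiguous (i, j) pairs covers every circular split.
The maximizer of |T_ij| yields the candidate change-points (i_c, j_c).

Index convention: i, j are cut positions in 0..N, the arc holding probes
i+1..j (half-open (i, j] on 0-based values).  i = 0 is allowed so that a
single change-point appears as (0, j) or (i, N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import scan_max_abs_t


class DegenerateSeriesError(ValueError):
    """Raised when the series has zero variance (s = 0)."""


class SeriesTooShortError(ValueError):
    """Raised when a series is too short for the requested scan."""


@dataclass
class ProbeSeries:
    """Ordered log2 ratios for one chromosome of one sample."""

    values: np.ndarray
    sample_id: str = ""
    chrom: str = ""
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != self.values.shape:
                raise ValueError("positions and values must align")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class MaxTResult:
    """Maximal-t scan outcome: T_max (signed) and candidate change-points."""

    t_max: float
    i_c: int
    j_c: int
    signed: bool = True

    @property
    def abs_t(self) -> float:
        return abs(self.t_max)


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


def t_statistic(series: ProbeSeries, i: int, j: int) -> float:
    """Evaluate T_ij for the arc (i, j] of the circularized series."""
    n = series.n
    if not (0 <= i < j <= n):
        raise ValueError(f"require 0 <= i < j <= N, got i={i}, j={j}, N={n}")
    k = j - i
    if k >= n:
        raise ValueError("arc must leave a non-empty complement (k <= N-1)")
    s = _sample_sd(series.values)
    if s == 0.0:
        raise DegenerateSeriesError("constant series: s = 0")
    total = float(np.sum(series.values))
    sij = float(np.sum(series.values[i:j]))
    return (sij / k - (total - sij) / (n - k)) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))


def max_t_scan(series: ProbeSeries, min_width: int = 2) -> MaxTResult:
    """Exhaustively locate argmax |T_ij| over arcs whose arc and complement
    both contain at least ``min_width`` probes.

    Equals a brute-force double loop exactly; ties break to the smallest
    (i, j) in lexicographic order.
    """
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    n = series.n
    if n < 2 * min_width:
        raise SeriesTooShortError(f"need N >= {2 * min_width}, got {n}")
    s = _sample_sd(series.values)
    if s == 0.0:
        raise DegenerateSeriesError("constant series: s = 0")
    prefix = np.concatenate(([0.0], np.cumsum(series.values, dtype=np.float64)))
    t, i, j = scan_max_abs_t(prefix, n, s, min_width)
    return MaxTResult(t_max=float(t), i_c=int(i), j_c=int(j))
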