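"""The eCBS engine: recursive change-point finding on circularized segments.

The engine has three stages.  (1) Pre-segmentation: a fast, permutation-free
coarse pass removes obvious copy-number shifts so the array's noise skewness
and kurtosis can be estimated without aberration bias; significance in this
pass is a fixed conservative normal-theory threshold and recursion stops
below 100 probes.  (2) Change-point finding: each segment is circularized,
the maximal-t scan proposes an arc (i_c, j_c), significance comes from the
GEV lookup (or the permutation fallback for short segments), and accepted
splits produce up to three subsegments that are recursed into.  The
statistic is always computed from the original log2 ratios, re-standardized
within the current segment; the pre-segmented data only feeds the moment
estimates.  (3) Edge effect correction: circularly joining a segment's ends
can manufacture spurious boundaries, so each proposed boundary must pass a
two-sample t-test on the probes flanking it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import RunConfig
from .maxt import ProbeSeries, max_t_scan
from .significance import Method, evaluate
from .xmodel import XtremeModel

logger = logging.getLogger(__name__)

_SK_RANGE = (-1.0, 1.0)
_KU_RANGE = (2.6, 5.6)


@dataclass(frozen=True)
class ArrayNoiseProfile:
    """Noise skewness/kurtosis estimated after removing large shifts."""

    sk: float
    ku: float
    n_probes_used: int
    n_segments_removed: int


@dataclass(frozen=True)
class SegmentRecord:
    """One constant-copy-number segment (probe indices 1-based inclusive)."""

    sample_id: str
    chrom: str
    start_index: int
    end_index: int
    start_pos: int
    end_pos: int
    n_probes: int
    seg_mean: float
    p_value: float | None


@dataclass(frozen=True)
class Split:
    """One accepted ternary split (for diagnostics and ROC scoring)."""

    boundaries: tuple[int, ...]  # surviving cut positions, 0-based
    p_value: float
    method: Method
    segment: tuple[int, int]  # [lo, hi) span the split was found in


@dataclass
class SegmentSet:
    """Disjoint, exhaustive segments of one chromosome plus the split log."""

    records: list[SegmentRecord]
    splits: list[Split] = field(default_factory=list)

    @property
    def boundaries(self) -> list[int]:
        """Internal cut positions, 0-based (count of preceding probes)."""
        cuts = []
        acc = 0
        for rec in self.records[:-1]:
            acc += rec.n_probes
            cuts.append(acc)
        return cuts


# ---------------------------------------------------------------------------
# Pre-segmentation and moment estimation


def _presegment_threshold(n: int, alpha: float) -> float:
    """Conservative normal-theory threshold on |T_max|: a two-sided
    Bonferroni bound over the ~N^2/2 arcs.  Correlation between arcs makes
    it conservative, which is the right bias for a coarse pre-pass."""
    n_pairs = n * (n - 1) / 2
    return float(stats.norm.isf(alpha / (2.0 * n_pairs)))


def _presegment_cuts(values: np.ndarray, cfg: RunConfig) -> list[int]:
    """Coarse recursive cuts; fixed threshold, no permutations, no edge
    correction, recursion stops below ``presegment_min_probes``."""
    cuts: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < max(cfg.presegment_min_probes, 2 * cfg.min_width):
            return
        seg = values[lo:hi]
        if float(np.std(seg, ddof=1)) == 0.0:
            return
        res = max_t_scan(ProbeSeries(seg), cfg.min_width)
        if abs(res.t_max) <= _presegment_threshold(n, cfg.presegment_alpha):
            return
        inner = [lo + c for c in (res.i_c, res.j_c) if 0 < c < n]
        pieces = [lo] + inner + [hi]
        cuts.extend(inner)
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, len(values))
    return sorted(set(cuts))


def _moments(values: np.ndarray) -> tuple[float, float]:
    m = values.mean()
    d = values - m
    m2 = np.mean(d * d)
    sk = float(np.mean(d**3) / m2**1.5)
    ku = float(np.mean(d**4) / m2**2)
    return sk, ku


def _clamp_profile(sk: float, ku: float) -> tuple[float, float]:
    sk = min(max(sk, _SK_RANGE[0]), _SK_RANGE[1])
    ku = min(max(ku, _KU_RANGE[0]), _KU_RANGE[1])
    if ku <= sk * sk + 1.0:  # keep the pair jointly feasible
        ku = min(max(sk * sk + 1.0 + 1e-3, ku), _KU_RANGE[1])
    return sk, ku


def pre_segment_and_estimate(
    series_list: list[ProbeSeries], cfg: RunConfig | None = None
) -> ArrayNoiseProfile:
    """Estimate noise skewness/kurtosis for one array.

    Runs the coarse pre-segmentation per chromosome, discards segments
    shorter than ``cfg.small_segment``, subtracts each remaining segment's
    mean, pools the residuals and returns their moment estimates, clamped
    to the lookup-table ranges.  Arrays with fewer than 200 usable probes
    fall back to a direct whole-array estimate.
    """
    cfg = cfg or RunConfig()
    total = sum(s.n for s in series_list)
    residuals = []
    removed = 0
    if total >= 200:
        for series in series_list:
            cuts = _presegment_cuts(series.values, cfg)
            edges = [0] + cuts + [series.n]
            for a, b in zip(edges[:-1], edges[1:]):
                if b - a < cfg.small_segment:
                    removed += 1
                    continue
                seg = series.values[a:b]
                residuals.append(seg - seg.mean())
    else:
        logger.warning(
            "only %d probes (< 200): whole-array moment estimate", total
        )
    if not residuals:
        if total >= 200:
            logger.warning("all probes discarded: whole-array moment estimate")
        pooled = np.concatenate([s.values - s.values.mean() for s in series_list])
    else:
        pooled = np.concatenate(residuals)
    if float(np.std(pooled)) == 0.0:
        logger.warning("degenerate (constant) array: normal-noise profile assumed")
        return ArrayNoiseProfile(0.0, 3.0, int(pooled.size), removed)
    sk, ku = _moments(pooled)
    sk, ku = _clamp_profile(sk, ku)
    return ArrayNoiseProfile(sk, ku, int(pooled.size), removed)


# ---------------------------------------------------------------------------
# Edge effect correction


def _window_test(left: np.ndarray, right: np.ndarray, edge_alpha: float) -> bool:
    """True if the boundary survives (the flanking means really differ).

    Welch two-sample t-test; a boundary whose window is too small to test
    is dropped, and exactly-constant windows compare means directly."""
    n1, n2 = left.size, right.size
    if n1 < 2 or n2 < 2:
        return False
    m1, m2 = float(left.mean()), float(right.mean())
    v1 = float(left.var(ddof=1))
    v2 = float(right.var(ddof=1))
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return m1 != m2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return p < edge_alpha


def edge_correct(
    series: ProbeSeries, boundaries: list[int], cfg: RunConfig | None = None
) -> list[int]:
    """Prune proposed cut positions whose flanking windows do not differ.

    For each candidate boundary a two-sample t-test compares the
    ``cfg.edge_window`` probes on either side, windows capped at the
    neighboring candidate boundaries and the segment ends.  Boundaries
    failing at ``cfg.edge_alpha`` are dropped; if all fail, the split is
    rejected ([] is returned).
    """
    cfg = cfg or RunConfig()
    n = series.n
    cand = sorted(b for b in boundaries if 0 < b < n)
    survivors = []
    for b in cand:
        prev = max([0] + [c for c in cand if c < b])
        nxt = min([n] + [c for c in cand if c > b])
        left = series.values[max(prev, b - cfg.edge_window): b]
        right = series.values[b: min(nxt, b + cfg.edge_window)]
        if _window_test(left, right, cfg.edge_alpha):
            survivors.append(b)
    return survivors


# ---------------------------------------------------------------------------
# Recursive change-point finding


def find_change_points(
    series: ProbeSeries,
    profile: ArrayNoiseProfile,
    model: XtremeModel,
    cfg: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentSet:
    """Segment one chromosome by recursive circular ternary splits."""
    cfg = cfg or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    values = series.values
    final: list[tuple[int, int, float | None]] = []
    splits: list[Split] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * cfg.min_width:
            final.append((lo, hi, None))
            return
        sub = values[lo:hi]
        if float(np.std(sub, ddof=1)) == 0.0:
            final.append((lo, hi, None))
            return
        sub_series = ProbeSeries(sub)
        scan = max_t_scan(sub_series, cfg.min_width)
        decision = evaluate(
            sub_series,
            scan,
            model,
            profile.sk,
            profile.ku,
            rng,
            alpha=cfg.alpha,
            gev_min_probes=cfg.gev_min_probes,
            n_perm=cfg.n_perm,
            early_stop=cfg.early_stop,
            min_width=cfg.min_width,
            force_permutation=cfg.force_permutation,
        )
        if not decision.significant:
            final.append((lo, hi, decision.p_value))
            return
        proposed = [c for c in (scan.i_c, scan.j_c) if 0 < c < n]
        if cfg.edge_correction:
            surviving = edge_correct(sub_series, proposed, cfg)
        else:
            surviving = proposed
        if not surviving:
            final.append((lo, hi, decision.p_value))
            return
        splits.append(
            Split(
                boundaries=tuple(lo + c for c in surviving),
                p_value=decision.p_value,
                method=decision.method,
                segment=(lo, hi),
            )
        )
        edges = [lo] + [lo + c for c in surviving] + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, series.n)
    final.sort()
    records = []
    for lo, hi, p in final:
        seg = values[lo:hi]
        pos = series.positions
        records.append(
            SegmentRecord(
                sample_id=series.sample_id,
                chrom=series.chrom,
                start_index=lo + 1,
                end_index=hi,
                start_pos=int(pos[lo]) if pos is not None else lo + 1,
                end_pos=int(pos[hi - 1]) if pos is not None else hi,
                n_probes=hi - lo,
                seg_mean=float(seg.mean()),
                p_value=p,
            )
        )
    return SegmentSet(records=records, splits=splits)


def segment_array(
    series_list: list[ProbeSeries],
    model: XtremeModel,
    cfg: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    profile: ArrayNoiseProfile | None = None,
) -> tuple[list[SegmentSet], ArrayNoiseProfile]:
    """Full pipeline for one sample: estimate the noise profile once from
    all chromosomes, then segment each chromosome with it."""
    cfg = cfg or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if profile is None:
        profile = pre_segment_and_estimate(series_list, cfg)
    return [
        find_change_points(s, profile, model, cfg, rng) for s in series_list
    ], profile
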