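"""Significance of candidate change-points.

Primary path: the p-value of an observed maximal-t statistic is
1 - gevcdf(T_max) under the GEV null looked up from the eXtreme model at
the segment's probe count and the array's noise skewness/kurtosis.  Below
``gev_min_probes`` (default 100) the GEV approximation is unreliable and a
plain permutation test with deterministic early stopping takes over; the
same permutation test doubles as a validation oracle for the lookup path.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from ._kernels import permutation_exceedances
from .gev import GEVParams, gev_cdf
from .maxt import DegenerateSeriesError, MaxTResult, ProbeSeries
from .xmodel import XtremeModel, lookup


class Method(enum.Enum):
    GEV_LOOKUP = "gev_lookup"
    PERMUTATION = "permutation"


@dataclass(frozen=True)
class SignificanceDecision:
    p_value: float
    method: Method
    t_max: float
    alpha: float
    significant: bool
    n_permutations: int = 0
    exceedances: int = 0


def gev_p_value(t_max: float, params: GEVParams) -> float:
    """p = 1 - gevcdf(|T_max|); strictly nonincreasing in t_max."""
    return float(1.0 - gev_cdf(abs(t_max), params))


def permutation_p_value(
    series: ProbeSeries,
    t_obs: float,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float = 0.01,
    early_stop: bool = True,
    min_width: int = 2,
) -> tuple[float, int, int]:
    """Add-one permutation p-value of |t_obs|.

    Returns (p, exceedances, permutations_examined).  With early stopping,
    terminates as soon as the exceedance count guarantees the final p-value
    would exceed ``alpha`` — i.e. once exceedances reach
    ceil(alpha * (1 + n_perm)), since (1 + X)/(1 + n_perm) is nondecreasing
    in X.  The reported conservative estimate then still satisfies
    p > alpha, and runs that would end significant are never cut short.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    if float(np.std(series.values, ddof=1)) == 0.0:
        raise DegenerateSeriesError("constant series: s = 0")
    t_abs = abs(t_obs)
    if early_stop:
        stop_count = int(math.ceil(alpha * (1 + n_perm)))
        stop_count = max(stop_count, 1)
    else:
        stop_count = n_perm + 1
    perms = rng.permuted(
        np.broadcast_to(series.values, (n_perm, series.n)), axis=1
    ).astype(np.float64)
    exceed, done = permutation_exceedances(perms, t_abs, min_width, stop_count)
    p = (1 + exceed) / (1 + done)
    return float(p), int(exceed), int(done)


def evaluate(
    series: ProbeSeries,
    scan: MaxTResult,
    model: XtremeModel,
    sk: float,
    ku: float,
    rng: np.random.Generator,
    alpha: float = 0.01,
    gev_min_probes: int = 100,
    n_perm: int = 1000,
    early_stop: bool = True,
    min_width: int = 2,
    force_permutation: bool = False,
) -> SignificanceDecision:
    """Route the decision: GEV lookup for N >= gev_min_probes (boundary
    inclusive), permutation fallback below."""
    use_gev = series.n >= gev_min_probes and not force_permutation
    if use_gev:
        params = lookup(model, series.n, sk, ku)
        p = gev_p_value(scan.t_max, params)
        return SignificanceDecision(
            p_value=p,
            method=Method.GEV_LOOKUP,
            t_max=scan.t_max,
            alpha=alpha,
            significant=p < alpha,
        )
    p, exceed, done = permutation_p_value(
        series,
        scan.t_max,
        n_perm=n_perm,
        rng=rng,
        alpha=alpha,
        early_stop=early_stop,
        min_width=min_width,
    )
    return SignificanceDecision(
        p_value=p,
        method=Method.PERMUTATION,
        t_max=scan.t_max,
        alpha=alpha,
        significant=p < alpha,
        n_permutations=done,
        exceedances=exceed,
    )
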