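"""Generalized Extreme Value distribution: evaluation and ML fitting.

The GEV with shape gamma, scale sigma > 0 and location mu has CDF
exp(-w^{-1/gamma}) on w = 1 + gamma (t - mu)/sigma > 0 for gamma != 0, and
the Gumbel form exp(-exp(-z)), z = (t - mu)/sigma, at gamma = 0.  It unifies
the Gumbel, Frechet and Weibull extreme-value families and is used here to
model the null distribution of the maximal-t statistic.

scipy's genextreme uses the opposite shape sign convention (c = -gamma);
this module presents the extreme-value-theory parameterization.  Fitting is
maximum likelihood, initialized from probability-weighted-moment (L-moment)
estimates, with jittered restarts on non-convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

_GUMBEL_EPS = 1e-6


@dataclass(frozen=True)
class GEVParams:
    """Shape gamma, scale sigma (> 0), location mu."""

    gamma: float
    sigma: float
    mu: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


class GEVFitError(RuntimeError):
    """Fit failed to converge; carries the best parameters seen so far."""

    def __init__(self, message: str, best: GEVParams | None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class GEVFit:
    params: GEVParams
    converged: bool
    log_likelihood: float
    ks_distance: float
    n_samples: int


def _frozen(params: GEVParams):
    if abs(params.gamma) < _GUMBEL_EPS:
        return stats.gumbel_r(loc=params.mu, scale=params.sigma)
    return stats.genextreme(-params.gamma, loc=params.mu, scale=params.sigma)


def gev_cdf(t, params: GEVParams):
    """GEV cumulative distribution function (Gumbel branch near gamma = 0)."""
    return _frozen(params).cdf(t)


def gev_pdf(t, params: GEVParams):
    return _frozen(params).pdf(t)


def gev_rvs(params: GEVParams, n: int, rng: np.random.Generator) -> np.ndarray:
    return _frozen(params).rvs(size=n, random_state=rng)


def _pwm_start(x: np.ndarray) -> GEVParams:
    """Probability-weighted-moment (Hosking) starting values."""
    xs = np.sort(x)
    n = xs.size
    j = np.arange(1, n + 1)
    b0 = xs.mean()
    b1 = float(np.sum((j - 1) / (n - 1) * xs) / n)
    b2 = float(np.sum((j - 1) * (j - 2) / ((n - 1) * (n - 2)) * xs) / n)
    l2 = 2 * b1 - b0
    l3 = 6 * b2 - 6 * b1 + b0
    t3 = l3 / l2
    z = 2.0 / (3.0 + t3) - math.log(2) / math.log(3)
    k = 7.8590 * z + 2.9554 * z * z  # Hosking's k = -gamma
    if abs(k) < 1e-8:
        sigma = l2 / math.log(2)
        mu = b0 - sigma * 0.5772156649015329
        return GEVParams(0.0, sigma, mu)
    gk = special.gamma(1.0 + k)
    sigma = l2 * k / ((1.0 - 2.0**-k) * gk)
    mu = b0 - sigma * (1.0 - gk) / k
    return GEVParams(-k, abs(sigma), mu)


def _loglik(x: np.ndarray, params: GEVParams) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = _frozen(params).logpdf(x)
    if not np.all(np.isfinite(ll)):
        return -np.inf
    return float(np.sum(ll))


def gev_fit(samples: np.ndarray, max_restarts: int = 5, seed: int = 0) -> GEVFit:
    """Maximum-likelihood GEV fit of a maximal-t sample.

    Requires >= 100 non-constant values.  Support violations during
    optimization act as a -inf log-likelihood barrier (scipy's internal
    penalized NLL); restarts jitter the PWM starting point.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 100:
        raise ValueError(f"need >= 100 samples to fit, got {x.size}")
    if float(np.std(x)) == 0.0:
        raise ValueError("constant sample: GEV fit undefined")

    start = _pwm_start(x)
    rng = np.random.default_rng(seed)
    best: GEVParams | None = None
    best_ll = -np.inf
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            g0, s0, m0 = start.gamma, start.sigma, start.mu
        else:
            g0 = start.gamma + rng.normal(scale=0.05)
            s0 = start.sigma * math.exp(rng.normal(scale=0.1))
            m0 = start.mu + rng.normal(scale=0.1 * start.sigma)
        try:
            c, loc, scale = stats.genextreme.fit(x, -g0, loc=m0, scale=s0)
            cand = GEVParams(-float(c), float(scale), float(loc))
        except Exception:
            continue
        ll = _loglik(x, cand)
        if ll > best_ll:
            best, best_ll = cand, ll
        if np.isfinite(ll):
            break
    if best is None or not np.isfinite(best_ll):
        raise GEVFitError("GEV fit did not converge after restarts", best)
    ks = float(stats.kstest(x, _frozen(best).cdf).statistic)
    return GEVFit(
        params=best,
        converged=True,
        log_likelihood=best_ll,
        ks_distance=ks,
        n_samples=int(x.size),
    )
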