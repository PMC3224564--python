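"""Pearson distribution system: null aCGH-like noise with chosen moments.

The Pearson system is the family of densities solving

    p'(x) / p(x) = (x - a) / (b2 x^2 + b1 x + b0),

parameterizable by its first four moments.  With the origin at the mean and
unit variance, the coefficients follow from skewness beta1 and (non-excess)
kurtosis beta2:

    A  = 10 beta2 - 12 beta1^2 - 18
    b0 = -(4 beta2 - 3 beta1^2) / A          (times theta2)
    b1 = a = -sqrt(theta2) beta1 (beta2 + 3) / A
    b2 = -(2 beta2 - 3 beta1^2 - 6) / A

The root structure of the denominator quadratic selects the Pearson type;
each type maps onto a classical distribution (beta, gamma, Student-t,
inverse-gamma, beta-prime) drawn through scipy, except type IV which has no
closed scipy form and is sampled by numerical inverse-CDF in the arctan
domain.  Every constructed sampler is self-checked: its population skewness
and kurtosis are recomputed (analytically or by quadrature) and must match
the request, so a classification or orientation bug cannot pass silently.
Samples are affinely standardized so the population mean is 0 and the
population variance 1, matching the simulation convention used throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

_A_TOL = 1e-9
_SYM_TOL = 1e-12


class InfeasibleMomentsError(ValueError):
    """Moments violate the feasibility bound beta2 > beta1^2 + 1."""


class DegenerateMomentsError(ValueError):
    """The coefficient denominator A = 10*beta2 - 12*beta1^2 - 18 vanishes;
    perturb beta2 slightly to move off the degenerate surface."""


class PearsonType(enum.Enum):
    NORMAL = "normal"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"


@dataclass(frozen=True)
class MomentSpec:
    """First four moments: mean/variance fixed at 0/1 in this package."""

    mean: float = 0.0
    variance: float = 1.0
    skewness: float = 0.0
    kurtosis: float = 3.0

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise InfeasibleMomentsError("variance must be positive")
        bound = self.skewness**2 + 1.0
        if self.kurtosis <= bound:
            raise InfeasibleMomentsError(
                f"kurtosis {self.kurtosis} <= skewness^2 + 1 = {bound}: "
                "no distribution has these moments"
            )


@dataclass(frozen=True)
class PearsonCoeffs:
    a: float
    b0: float
    b1: float
    b2: float
    A: float
    pearson_type: PearsonType


def moments_to_coeffs(spec: MomentSpec) -> PearsonCoeffs:
    """Map (skewness, kurtosis) to the Pearson ODE coefficients and type."""
    b1sq = spec.skewness**2
    beta2 = spec.kurtosis
    theta2 = spec.variance
    A = 10.0 * beta2 - 12.0 * b1sq - 18.0
    if abs(A) < _A_TOL:
        raise DegenerateMomentsError(
            f"A = 10*ku - 12*sk^2 - 18 = {A:.3g} vanishes at "
            f"(sk={spec.skewness}, ku={beta2}); perturb kurtosis slightly"
        )
    b0 = -theta2 * (4.0 * beta2 - 3.0 * b1sq) / A
    b1 = -math.sqrt(theta2) * spec.skewness * (beta2 + 3.0) / A
    b2 = -(2.0 * beta2 - 3.0 * b1sq - 6.0) / A
    return PearsonCoeffs(
        a=b1, b0=b0, b1=b1, b2=b2, A=A, pearson_type=_classify(spec, b0, b1, b2)
    )


def _classify(spec: MomentSpec, b0: float, b1: float, b2: float) -> PearsonType:
    if abs(spec.skewness) < _SYM_TOL:
        if abs(spec.kurtosis - 3.0) < _SYM_TOL:
            return PearsonType.NORMAL
        return PearsonType.II if spec.kurtosis < 3.0 else PearsonType.VII
    if abs(b2) < _A_TOL:
        return PearsonType.III
    kappa = b1 * b1 / (4.0 * b0 * b2)
    if kappa < 0.0:
        return PearsonType.I
    if abs(kappa - 1.0) < 1e-10:
        return PearsonType.V
    if kappa < 1.0:
        return PearsonType.IV
    return PearsonType.VI


# ---------------------------------------------------------------------------
# Samplers


class PearsonSampler:
    """Frozen sampler for one (skewness, kurtosis) pair, standardized to
    population mean 0 and variance 1.  Reuse across draws; construction does
    the type classification, parameter solving and a moment self-check."""

    def __init__(self, spec: MomentSpec):
        self.spec = spec
        self.coeffs = moments_to_coeffs(spec)
        # canonical orientation: positive skew; mirror at draw time
        self._flip = spec.skewness < 0
        sk = abs(spec.skewness)
        ku = spec.kurtosis
        self._impl = _build_impl(self.coeffs.pearson_type, sk, ku)
        self._self_check(sk, ku)

    def _self_check(self, sk: float, ku: float) -> None:
        got_sk, got_ku = self._impl.shape_moments()
        if not (math.isclose(got_sk, sk, abs_tol=5e-3) and
                math.isclose(got_ku, ku, abs_tol=5e-2)):
            raise RuntimeError(
                f"Pearson sampler self-check failed for (sk={sk}, ku={ku}): "
                f"constructed distribution has (sk={got_sk:.4f}, ku={got_ku:.4f})"
            )

    @property
    def pearson_type(self) -> PearsonType:
        return self.coeffs.pearson_type

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        x = self._impl.draw(n, rng)
        if self._flip:
            x = -x
        return self.spec.mean + math.sqrt(self.spec.variance) * x


def sample(spec: MomentSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. values with the requested first four moments."""
    x = get_sampler(spec.skewness, spec.kurtosis).draw(n, rng)
    return spec.mean + math.sqrt(spec.variance) * x


@lru_cache(maxsize=2048)
def get_sampler(skewness: float, kurtosis: float) -> PearsonSampler:
    return PearsonSampler(MomentSpec(skewness=float(skewness), kurtosis=float(kurtosis)))


class _Impl:
    """One concrete standardized sampler (canonical positive-skew form)."""

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def shape_moments(self) -> tuple[float, float]:  # pragma: no cover
        raise NotImplementedError


class _Normal(_Impl):
    def draw(self, n, rng):
        return rng.standard_normal(n)

    def shape_moments(self):
        return 0.0, 3.0


class _ScipyDist(_Impl):
    """Standardized wrapper around a frozen scipy distribution."""

    def __init__(self, dist):
        m, v, s, k = dist.stats(moments="mvsk")
        self._dist = dist
        self._mean = float(m)
        self._sd = math.sqrt(float(v))
        self._sk = float(s)
        self._ku = float(k) + 3.0  # scipy reports excess kurtosis

    def draw(self, n, rng):
        return (self._dist.rvs(size=n, random_state=rng) - self._mean) / self._sd

    def shape_moments(self):
        return self._sk, self._ku


class _TypeIV(_Impl):
    """Pearson type IV via inverse-CDF in phi = arctan space.

    With x = tan(phi), the density is proportional to
    cos^{2m-2}(phi) * exp(-nu * phi) on (-pi/2, pi/2), where
    m = (r + 2)/2, r = 6(ku - sk^2 - 1)/(2 ku - 3 sk^2 - 6) and
    nu = -r (r - 2) sk / sqrt(16 (r - 1) - sk^2 (r - 2)^2).
    The CDF is tabulated on a dense grid and inverted by interpolation;
    standardization constants come from quadrature of the same density.
    """

    _M = 200_001

    def __init__(self, sk: float, ku: float):
        r = 6.0 * (ku - sk * sk - 1.0) / (2.0 * ku - 3.0 * sk * sk - 6.0)
        m = (r + 2.0) / 2.0
        nu = -r * (r - 2.0) * sk / math.sqrt(
            16.0 * (r - 1.0) - sk * sk * (r - 2.0) ** 2
        )
        phi = np.linspace(-np.pi / 2, np.pi / 2, self._M)
        with np.errstate(over="ignore"):
            logg = 2.0 * (m - 1.0) * np.log(np.maximum(np.cos(phi), 1e-300)) - nu * phi
        g = np.exp(logg - logg.max())
        cdf = np.concatenate(([0.0], np.cumsum((g[1:] + g[:-1]) * 0.5)))
        norm = cdf[-1]
        cdf /= norm
        g /= norm
        x = np.tan(np.clip(phi, -np.pi / 2 + 1e-12, np.pi / 2 - 1e-12))
        w = g / g.sum()
        mom = [float(np.sum(w * x**p)) for p in (1, 2, 3, 4)]
        mean = mom[0]
        var = mom[1] - mean**2
        mu3 = mom[2] - 3 * mean * mom[1] + 2 * mean**3
        mu4 = mom[3] - 4 * mean * mom[2] + 6 * mean**2 * mom[1] - 3 * mean**4
        self._sk = mu3 / var**1.5
        self._ku = mu4 / var**2
        self._mean = mean
        self._sd = math.sqrt(var)
        self._phi = phi
        self._cdf = cdf

    def draw(self, n, rng):
        u = rng.random(n)
        phi = np.interp(u, self._cdf, self._phi)
        x = np.tan(np.clip(phi, -np.pi / 2 + 1e-12, np.pi / 2 - 1e-12))
        return (x - self._mean) / self._sd

    def shape_moments(self):
        return self._sk, self._ku


def _quadratic_roots(b2: float, b1: float, b0: float) -> tuple[float, float]:
    disc = b1 * b1 - 4.0 * b2 * b0
    if disc < 0:
        raise ValueError("quadratic has no real roots")
    sq = math.sqrt(disc)
    r1 = (-b1 - sq) / (2.0 * b2)
    r2 = (-b1 + sq) / (2.0 * b2)
    return (min(r1, r2), max(r1, r2))


def _beta_from_roots(sk: float, ku: float) -> _ScipyDist:
    """Types I and II: density |x-a1|^{A1} |a2-x|^{A2} on (a1, a2)."""
    c = moments_to_coeffs(MomentSpec(skewness=sk, kurtosis=ku))
    a1, a2 = _quadratic_roots(c.b2, c.b1, c.b0)
    e1 = (a1 - c.a) / (c.b2 * (a1 - a2))
    e2 = (a2 - c.a) / (c.b2 * (a2 - a1))
    alpha, beta = e1 + 1.0, e2 + 1.0
    if alpha <= 0 or beta <= 0:
        raise RuntimeError(f"beta exponents non-positive for (sk={sk}, ku={ku})")
    return _ScipyDist(stats.beta(alpha, beta, loc=a1, scale=a2 - a1))


def _build_impl(ptype: PearsonType, sk: float, ku: float) -> _Impl:
    if ptype is PearsonType.NORMAL:
        return _Normal()
    if ptype in (PearsonType.I, PearsonType.II):
        return _beta_from_roots(sk, ku)
    if ptype is PearsonType.VII:
        # Student-t scaled to unit variance; ku = 3 + 6/(df - 4)
        df = 4.0 + 6.0 / (ku - 3.0)
        return _ScipyDist(stats.t(df, scale=math.sqrt((df - 2.0) / df)))
    if ptype is PearsonType.III:
        # gamma on the b2 = 0 line: shape from skewness, sk = 2/sqrt(shape)
        shape = 4.0 / (sk * sk)
        return _ScipyDist(stats.gamma(shape))
    if ptype is PearsonType.V:
        # inverse gamma: sk^2 = 16 (a - 2) / (a - 3)^2, take the root > 4
        coeffs = np.array([sk * sk, -6.0 * sk * sk - 16.0, 9.0 * sk * sk + 32.0])
        roots = np.roots(coeffs)
        a = float(max(r.real for r in roots if abs(r.imag) < 1e-9))
        if a <= 4.0:
            raise RuntimeError(f"type V shape {a} <= 4 for sk={sk}")
        return _ScipyDist(stats.invgamma(a))
    if ptype is PearsonType.VI:
        c = moments_to_coeffs(MomentSpec(skewness=sk, kurtosis=ku))
        a1, a2 = _quadratic_roots(c.b2, c.b1, c.b0)
        e1 = (a1 - c.a) / (c.b2 * (a1 - a2))
        e2 = (a2 - c.a) / (c.b2 * (a2 - a1))
        # support (a2, inf) when both roots sit left of the mean
        bp_a = e2 + 1.0
        bp_b = -(e1 + e2) - 1.0
        if bp_a <= 0 or bp_b <= 4.0:
            raise RuntimeError(f"type VI parameters out of range for (sk={sk}, ku={ku})")
        return _ScipyDist(stats.betaprime(bp_a, bp_b, loc=a2, scale=a2 - a1))
    if ptype is PearsonType.IV:
        return _TypeIV(sk, ku)
    raise AssertionError(f"unhandled Pearson type {ptype}")
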