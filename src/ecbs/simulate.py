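"""Validation simulations: piecewise-constant aCGH series with known truth.

Model 1: 150 probes, four change-points at cut positions {50, 70, 80, 100},
segment means (0, cv, -cv, cv, 0) with Gaussian N(m_i, v^2) noise; c scales
the aberration amplitude in noise-sd units.  Model 2: 1,500 probes with one
aberration window of width k at location l (mean c*v inside, 0 outside) and
noise drawn from the Pearson system at a chosen skewness/kurtosis, scaled
to sd v.  The ROC study embeds a 15-probe aberration at the chromosome edge
(l = 0), segments matched signal and null replicates with both significance
methods, and reports sensitivity/specificity over a grid of alpha levels.

Change-point positions are expressed as 0-based cut positions: boundary b
means the mean shifts between probe b and probe b+1 (equivalently b probes
precede the cut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .maxt import ProbeSeries
from .pearson import get_sampler
from .segmentation import find_change_points, pre_segment_and_estimate
from .xmodel import XtremeModel

MODEL1_N = 150
MODEL1_BOUNDARIES = (50, 70, 80, 100)
MODEL2_N = 1500


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated chromosome."""

    n_probes: int
    boundaries: tuple[int, ...]
    segment_means: tuple[float, ...]
    noise_sd: float
    amplitude_factor: float
    noise_sk: float = 0.0
    noise_ku: float = 3.0

    def mean_vector(self) -> np.ndarray:
        edges = (0,) + self.boundaries + (self.n_probes,)
        out = np.empty(self.n_probes)
        for m, a, b in zip(self.segment_means, edges[:-1], edges[1:]):
            out[a:b] = m
        return out


def model1(c: float, v: float, seed: int) -> tuple[ProbeSeries, SimTruth]:
    """150-probe series with four change-points at {50, 70, 80, 100} and
    segment means (0, cv, -cv, cv, 0)."""
    if v < 0:
        raise ValueError("v must be >= 0")
    cv = c * v
    truth = SimTruth(
        n_probes=MODEL1_N,
        boundaries=MODEL1_BOUNDARIES,
        segment_means=(0.0, cv, -cv, cv, 0.0),
        noise_sd=v,
        amplitude_factor=c,
    )
    rng = np.random.default_rng(seed)
    values = truth.mean_vector() + (rng.standard_normal(MODEL1_N) * v if v > 0 else 0.0)
    return ProbeSeries(values, sample_id="sim", chrom="model1"), truth


def model2(
    c: float,
    v: float,
    k: int = 15,
    l: int = 0,
    noise_sk: float = 0.0,
    noise_ku: float = 3.0,
    seed: int = 0,
    n_probes: int = MODEL2_N,
) -> tuple[ProbeSeries, SimTruth]:
    """Series with mean c*v on the k-wide window starting at cut l, 0
    elsewhere; Pearson-system noise scaled to sd v.  l = 0 puts the
    aberration at the chromosome edge (single change-point at k);
    l = (N - k) // 2 centers it (two change-points)."""
    if not 0 <= l <= n_probes - k:
        raise ValueError("need 0 <= l <= N - k")
    cv = c * v
    boundaries = tuple(b for b in (l, l + k) if 0 < b < n_probes)
    edges = (0,) + boundaries + (n_probes,)
    means = tuple(
        cv if (a >= l and b <= l + k) else 0.0
        for a, b in zip(edges[:-1], edges[1:])
    )
    truth = SimTruth(
        n_probes=n_probes,
        boundaries=boundaries,
        segment_means=means,
        noise_sd=v,
        amplitude_factor=c,
        noise_sk=noise_sk,
        noise_ku=noise_ku,
    )
    rng = np.random.default_rng(seed)
    if v > 0:
        noise = get_sampler(noise_sk, noise_ku).draw(n_probes, rng) * v
    else:
        noise = 0.0
    return ProbeSeries(truth.mean_vector() + noise, sample_id="sim", chrom="model2"), truth


@dataclass
class ROCResult:
    alphas: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_signal: int
    n_null: int

    @property
    def auc(self) -> float:
        """Area under sensitivity vs (1 - specificity), trapezoidal, with
        (0,0) and (1,1) endpoints."""
        fpr = np.concatenate(([0.0], 1.0 - self.specificity, [1.0]))
        tpr = np.concatenate(([0.0], self.sensitivity, [1.0]))
        order = np.argsort(fpr, kind="stable")
        return float(np.trapezoid(tpr[order], fpr[order]))


def _detected(splits, truth: SimTruth, alpha: float, tol: int) -> bool:
    """All true boundaries matched within +/- tol probes by boundaries of
    splits significant at alpha."""
    found = [
        b
        for s in splits
        if s.p_value < alpha
        for b in s.boundaries
    ]
    return all(any(abs(b - t) <= tol for b in found) for t in truth.boundaries)


def _false_positive(splits, alpha: float) -> bool:
    return any(s.p_value < alpha for s in splits)


def roc_study(
    method: str,
    model: XtremeModel,
    c: float = 1.5,
    noise_sk: float = 0.0,
    noise_ku: float = 3.0,
    n_rep: int = 500,
    seed: int = 0,
    alphas=(0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5),
    cfg: RunConfig | None = None,
    match_tol: int = 2,
    k: int = 15,
    l: int = 0,
    n_probes: int = MODEL2_N,
) -> ROCResult:
    """Sensitivity/specificity of change-point detection across alphas.

    Each replicate pairs one aberration-bearing and one null series built
    from the same seed stream; segmentation runs once at max(alphas) and
    the recorded split p-values are thresholded at each alpha.  ``method``
    is "gev" or "permutation" (the latter forces the permutation test at
    every segment size, serving as the reference path).
    """
    if method not in ("gev", "permutation"):
        raise ValueError("method must be 'gev' or 'permutation'")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    alphas = np.asarray(sorted(alphas), dtype=float)
    base = cfg or RunConfig()
    run_cfg = RunConfig(
        alpha=float(alphas[-1]),
        gev_min_probes=base.gev_min_probes,
        min_width=base.min_width,
        small_segment=base.small_segment,
        edge_window=base.edge_window,
        edge_alpha=base.edge_alpha,
        n_perm=base.n_perm,
        early_stop=base.early_stop,
        force_permutation=(method == "permutation"),
    )
    ss = np.random.SeedSequence(seed)
    sens_hits = np.zeros(alphas.size)
    fp_hits = np.zeros(alphas.size)
    for rep in range(n_rep):
        rep_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        signal, truth = model2(
            c, 1.0, k=k, l=l, noise_sk=noise_sk, noise_ku=noise_ku,
            seed=rep_seed, n_probes=n_probes,
        )
        null, _ = model2(
            0.0, 1.0, k=k, l=l, noise_sk=noise_sk, noise_ku=noise_ku,
            seed=rep_seed + 1, n_probes=n_probes,
        )
        rng = np.random.default_rng(rep_seed + 2)
        for series, is_signal in ((signal, True), (null, False)):
            prof = pre_segment_and_estimate([series], run_cfg)
            segset = find_change_points(series, prof, model, run_cfg, rng)
            if is_signal:
                for a_idx, alpha in enumerate(alphas):
                    if _detected(segset.splits, truth, alpha, match_tol):
                        sens_hits[a_idx] += 1
            else:
                for a_idx, alpha in enumerate(alphas):
                    if _false_positive(segset.splits, alpha):
                        fp_hits[a_idx] += 1
    return ROCResult(
        alphas=alphas,
        sensitivity=sens_hits / n_rep,
        specificity=1.0 - fp_hits / n_rep,
        n_signal=n_rep,
        n_null=n_rep,
    )
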