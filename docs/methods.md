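# Methods

## Problem and model

Array-CGH measures DNA copy number as log2 ratios r_1…r_N along ordered
genomic probes.  Copy-number alterations appear as shifts in the mean of a
contiguous probe run.  Segmentation asks: where does the mean change?

Circular binary segmentation answers recursively.  A segment's two ends are
joined into a circle and every arc (i, j] is scored against its complement
with the two-sample t-like statistic

T_ij = (S_ij/k − (S_N − S_ij)/(N − k)) / (s √(1/k + 1/(N − k))),

S_ij the arc sum, k = j − i, s the segment's sample standard deviation
((n−1) denominator).  T_max = max |T_ij| is the test statistic; its
maximizers (i_c, j_c) are the candidate change-points.  If T_max is
significant the segment is cut at the surviving boundaries (up to a ternary
split) and the procedure recurses until nothing significant remains.

The expensive question is the null distribution of T_max.  This package
models it with the Generalized Extreme Value (GEV) family.  T_max is a
maximum over ~N²/2 correlated arc statistics; extreme-value theory for
dependent sequences motivates (but does not prove) GEV shape for large N,
so adequacy is demonstrated empirically: at desk scale the KS distance
between 10⁴ simulated null T_max values and the fitted GEV is below 0.02
(the test suite recomputes this).

## The eXtreme model

Null series are drawn from the Pearson distribution system, which realizes
any feasible (skewness β₁, kurtosis β₂) pair with mean 0, variance 1 —
mean and scale are irrelevant because T_ij standardizes them away.  The
reference grid is N ∈ {10…100 step 10, 100…1000 step 100, 1000…10000 step
1000}, β₁ ∈ [−1, 1] step 0.1, β₂ ∈ [2.6, 5.6] step 0.2 (kurtosis is
non-excess throughout: normal = 3).  Per cell, many null series are
simulated, T_max computed for each, and a GEV fitted by maximum likelihood;
the (γ, σ, μ) triples populate three 3-D tables.  Queries interpolate
trilinearly from the 8 surrounding cells — justified because the fitted
surfaces vary smoothly (the build asserts relative jumps of σ and μ between
adjacent cells stay under 25%) — and out-of-range queries clamp to the
boundary with a logged warning.

Two grid cells, (β₁ = ±1, β₂ = 3.0), sit exactly on the degenerate surface
A = 10β₂ − 12β₁² − 18 = 0 where the moment→coefficient correspondences
blow up; the builder perturbs kurtosis by 10⁻⁶ there and flags the cell.

### Pearson sampling

The coefficients of p′/p = (x − a)/(b₂x² + b₁x + b₀) follow from the
moments (a = b₁, the standard identity with the origin at the mean; b₁
carries a √θ₂ factor so it has the dimension of x).  The root structure of
the denominator selects the type, and each type is drawn through an exact
transform of a classical distribution: beta for types I/II, gamma for III,
unit-variance Student-t for VII, inverse-gamma for V, beta-prime for VI.
Type IV (most of the grid's upper half) has no closed scipy form; with
x = tan φ its density becomes cos^{2m−2}(φ)·e^{−νφ} on (−π/2, π/2), which
is tabulated on a 200,001-point grid and sampled by inverse-CDF
interpolation.  Every constructed sampler recomputes its population
skewness/kurtosis (analytically or by quadrature) and raises if they miss
the request by more than 5·10⁻³ / 5·10⁻², so classification or orientation
bugs cannot pass silently.  Negative skewness is sampled by mirroring.

### GEV fitting

Maximum likelihood via scipy's genextreme (shape c = −γ), initialized from
probability-weighted-moment (Hosking) estimates, with up to 5 jittered
restarts; support violations act as a −∞ log-likelihood barrier inside the
optimizer.  |γ| < 10⁻⁶ is evaluated on the Gumbel branch to avoid
cancellation.  Fits return a converged flag, the log-likelihood and a KS
distance as diagnostics; fewer than 100 samples or constant samples are
rejected.

## Significance evaluation

For a segment of N probes, p = 1 − GEV_cdf(|T_max|) with parameters looked
up at (N, sk, ku).  The GEV approximation degrades for short series, so
below `gev_min_probes` = 100 a plain permutation test takes over:
p = (1 + #exceedances)/(1 + #permutations), the add-one estimator that
cannot return 0.  Early stopping is deterministic, not probabilistic: the
run stops as soon as the exceedance count alone guarantees the final
p-value would exceed α, so any run that could end significant is never cut
short and the reported conservative estimate still exceeds α.  Default
α = 0.01; all thresholds are config-exposed.

## Noise-profile estimation (pre-segmentation)

Skewness/kurtosis estimated directly from an array are biased by the very
aberrations being sought, so a coarse permutation-free pass removes large
shifts first.  Per chromosome, segments are split recursively while
|T_max| exceeds a fixed conservative threshold — the two-sided Bonferroni
normal quantile z_{α₀/(2·N(N−1)/2)} with α₀ = 0.001 over the ~N²/2 arcs;
correlation between arcs makes this conservative, the right bias for a
pre-pass — with no edge correction, and recursion stops below 100 probes
(the pass is deliberately low-resolution).  Segments shorter than
`small_segment` = 15 probes are discarded, the surviving segments'
means subtracted, and the pooled residuals give moment estimates of sk and
ku, clamped to the table ranges (and kept jointly feasible,
ku > sk² + 1).  Arrays with fewer than 200 usable probes fall back to a
whole-array estimate with a warning.  The 15-probe discard threshold
matches the aberration width used in the power studies; 100 probes matches
the GEV routing minimum.

The maximal-t statistic of the actual segmentation is always computed from
the original log2 ratios; the pre-segmented data only feeds the moment
estimates.

## Edge-effect correction

Circularly joining a segment's ends can manufacture a boundary between two
equal-mean ends.  Each proposed boundary is therefore tested with a Welch
two-sample t-test on the `edge_window` = 25 probes flanking it, windows
capped at the neighboring candidate boundary and the segment ends;
boundaries failing at `edge_alpha` = 0.01 are dropped, and if all fail the
split is rejected.  A boundary whose window holds fewer than 2 probes
cannot be validated and is dropped — without this rule, chance extremes in
the first or last probe produce 1-probe segments that no test can refute.
Exactly constant windows (noise-free data) compare means directly.

## Segment records

Output segments tile each chromosome (1-based inclusive probe indices).
Every output segment is terminal by construction; its p_value field holds
the final non-significant test on that segment, and is NA when the segment
was too short or degenerate to test.  Accepted splits (boundary set,
p-value, significance method) are kept in a separate log used by the ROC
study and diagnostics.

## Simulation designs

* Model 1: N = 150, change-points at cut positions {50, 70, 80, 100},
  segment means (0, cv, −cv, cv, 0), Gaussian noise sd v; c ∈ {2, 3, 4}
  are the standard amplitudes.  Boundaries are reported as 0-based cut
  positions (number of probes before the cut).
* Model 2: N = 1500, one aberration window of width k (default 15) at
  location l — l = 0 puts it at the chromosome edge (single change-point),
  l = (N − k)/2 centers it (two change-points) — mean c·v inside, 0
  outside, noise from the Pearson system at chosen (sk, ku) scaled to sd v.
* ROC study: paired signal (c > 0) and null (c = 0) replicates from model
  2 at the edge; segmentation runs once per replicate at the most
  permissive α on the grid and the recorded split p-values are thresholded
  at each α (nested splits are therefore conditioned on the permissive run,
  an approximation shared identically by both methods).  Detection =
  every true boundary matched within ±2 probes by a significant split
  boundary; a null replicate counts against specificity when any split is
  significant.  AUC is trapezoidal over the measured (FPR, TPR) points
  plus the (0,0) and (1,1) endpoints.

The generator emulates piecewise-constant means with i.i.d. noise of
controlled third and fourth moments.  It does not emulate probe-to-probe
correlation, wave artifacts, variable probe spacing, or outlier probes
beyond what the chosen kurtosis implies — so passing tests demonstrate
correctness of the statistical machinery under the stated noise families,
not robustness to structured artifacts in real arrays.

## Desk-scale study sizes

The full reference grid (~9,400 cells × 10⁴ replicates) is a batch job.
The package's desk preset — N ∈ {100, 150, 250, 400, 700, 1000, 1500},
sk ∈ {−0.3, 0, 0.3, 0.6, 0.9}, ku ∈ {2.6, 3.0, 3.5, 4.2, 5.0}, 1500
replicates per cell — builds in ~3 minutes on one CPU and is what the test
suite and acceptance script use for pipeline-level checks.  The check that
compares lookup p-values directly against a permutation oracle builds an
N = 250 slab (7 × 7 skewness/kurtosis cells spanning the sampling
distribution of 250-probe moment estimates) at the full 10⁴-replicate
scale, so model coarseness is not conflated with method error, and indexes
it by each series' estimated moments — the pipeline's own mechanism, and
the only fair match for a permutation null that conditions on the observed
values (a lookup at fixed (0, 3) cannot track the per-series permutation
null no matter how well it is built).  Concordance and ROC checks use 500
series / 250 paired replicates with reduced permutation budgets; the
acceptance script prints every problem size it used next to the value.

## Numerical choices and limitations

* Scan ties break to the lexicographically smallest (i, j); arcs (0, m)
  and (m, N) are exact complements with opposite T, so their tie is real
  and broken deterministically.
* min_width = 2 probes per arm: both arcs need a variance contribution.
* Per-cell build RNG streams spawn from (build_seed, cell index), so cell
  results are independent of build order and partial rebuilds reproduce.
* Model JSON round-trips bit-exactly (decimal strings reproduce IEEE
  doubles); version and replicate count are stored and checked.
* Interpolation on the N axis is linear in N within the grid; μ grows
  roughly like √log of the arc count, so the grid refines small N where
  curvature is largest.
* Queries outside the grid clamp rather than extrapolate; heavy-tailed
  arrays whose estimated kurtosis exceeds 5.6 are therefore evaluated at
  the table edge, which is slightly anticonservative for more extreme
  tails.
* The permutation fallback, not a hybrid tail approximation, handles short
  segments: permutation is exact and cheap at small N.
* Kurtosis estimates have large sampling error on heavy-tailed arrays
  (their variance involves the 8th moment, which may not exist at the
  grid's upper edge); the lookup tolerates this because the tables vary
  smoothly, but per-array profiles should be read as rough indices, not
  precise moment measurements.
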