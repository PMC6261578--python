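# Methods

## Statistical model

A calibration experiment scores foci in samples of *n* cells irradiated at
design doses *x₁ … x_d*. For sample *j* at dose *i* the absolute focus
count *Y_ij* has mean *n μ_i* with *μ_i = A + B x_i* (identity link; a
quadratic term *C x_i²* may be added). Counts are treated as quasi-Poisson:
only the first two moments are assumed, with Var(*Y*) = φ·E(*Y*). The
dispersion index φ absorbs intra- and inter-individual variation,
scoring-process noise and other unstructured excess variance; for manually
scored γ-H2AX data it typically sits between 20 and 60, and the consensus
default used whenever a curve arrives without its own φ is the conservative
value **60**.

Because the Poisson score equations for (A, B) are proportional to 1/φ,
the point estimates equal plain Poisson estimates; φ only enters the
standard errors, as SE = √φ̂ · SE_Poisson, with
φ̂ = 1/(N−p) Σ (Y_ij − nμ̂_i)²/(nμ̂_i) (Pearson statistic over N − p
degrees of freedom; p = 2 for a linear curve, 3 for quadratic or for the
shared-intercept two-time model). Unequal cell numbers per sample are
supported by carrying n per row through the design and the Pearson sum.

The two-time model *E(y) = a + b₁x + b₂x·1{t = 24h}* shares the
background yield between the 1 h and 24 h curves — without radiation there
is no "time after exposure", so the intercept is a property of the
experiment, not of the time point. Per-time curves follow exactly as
(A, B) = (a, b₁) and (a, b₁ + b₂); the SE of b₁ + b₂ uses the full
parameter covariance (this is ordinary GLM output, not the delta-method
shortcut used later for dose).

Whether donors need explicit modelling is decided by a sequential analysis
of deviance (intercept → dose → dose×time → donor): the donor deviance
drop divided by the full model's Pearson φ̂ is referred to χ² with
(donors − 1) df. In data of this kind the intra-individual variation
swamps the inter-individual variation, and the donor term is absorbed by
the overdispersion.

## Fitting algorithm

Identity-link Poisson regression is fitted by Fisher scoring, which here
reduces to iteratively reweighted least squares with weights 1/μ̂ and
working response Y. The identity link does not respect the positivity of
the Poisson mean, so steps are halved until all fitted means stay
positive; if no admissible step exists, or the fit converges to a
non-positive mean at a design dose, the fit fails loudly rather than
truncating. Starting values come from least squares of counts on the
design (falling back to a flat curve through the grand mean if that start
is infeasible). Convergence requires a relative parameter change below
1e-8; the iteration cap is 500, sized for donor-dummy models with ~34
parameters, where the identity-link iteration contracts slowly (factor
≈ 0.9 per step) and legitimately needs a couple of hundred iterations.
The tests cross-check the fit against statsmodels' GLM and against a
brute-force grid maximizer of the likelihood on tiny datasets.

## Dose estimation and its uncertainty

Dose is estimated by inverting the linear curve at the observed customer
yield, x\* = (y\* − Â)/B̂. Negative estimates are reported as-is (annotated
as consistent with an unexposed sample); clipping at zero would bias any
averaging of estimates. Quadratic curves are not inverted in the main
workflow — the variance contributed by Ĉ can swamp every other source of
uncertainty near saturation — but the variance decomposition supports them
for exactly that demonstration, using implicit differentiation of
A + Bx + Cx² = y (the smaller positive root is taken for saturating
curves, C < 0; the partials are tested against numerical differentiation).

The reported variance is the delta method without covariance terms:
SE²(x\*) = SE²(Â)/B̂² + (y\*−Â)²SE²(B̂)/B̂⁴ + φ y\*/(n\* B̂²). The three
summands are returned as an additive uncertainty budget (intercept, slope,
sampling). Omitting the covariances is deliberate and matches the
established triage practice this workflow follows; no option to include
them is offered. The sampling term uses the plug-in variance φ y\*/n\*,
which is exactly zero at y\* = 0 — retained literally, since the parameter
terms still contribute there. φ is resolved as: explicit argument → the
curve's fitted φ → consensus 60 (with a warning).

## Validation and the reference curve

Reference yields are compared with prediction intervals
Â + B̂x ± q·√(φ(Â+B̂x)/n′). The negative control uses q = 3, the positive
q = 2: a slope bias has far more severe consequences than a small
background mismatch, so the positive control is held to the stricter
check. A yield exactly on an endpoint counts as inside — conservative
toward retaining an established curve. There is one decision for the
curve: discard if either control is outside. Replicate controls at a
common dose are pooled by adding counts and cells; 0 Gy controls may be
pooled across time labels. φ is never estimated from the two reference
points (two observations cannot support a Pearson estimate); it comes from
the curve or the consensus value.

On discard, the curve through (0, y₀) and (r, y_r) takes over:
Ã = y₀ with SE √(φy₀/n₀), B̃ = (y_r − y₀)/r with
SE (1/r)·√(φ(y₀/n₀ + y_r/n_r)). These SEs are necessarily larger than
those of a full calibration experiment, but the two-point curve is
plausibly unbiased under the customer's scoring conditions, which is what
matters for triage. The ratio (Â + B̂x_r)/y_r is computed as a bias
diagnostic only and never applied to estimates automatically.

Workflow resolution: calibration data (when supplied) win over a typed-in
curve, because a fitted curve carries SEs and φ; no reference samples
means the curve is used uncontested with a NO_REFERENCE warning; missing
SEs enter as zero and a missing φ as 60, each with exactly one
machine-readable warning code. Per-sample time labels select among
supplied per-time curves, and a label without a curve is an error rather
than a silent fallback.

## Synthetic data generator

The generator emulates the moment structure the framework assumes: counts
with mean n(A + Bx) and variance φ times that, drawn negative-binomially
with size = mean/(φ−1) (Poisson at φ = 1). The default scenario is a
two-time experiment with 339 samples of 500 cells at doses 0–4 Gy
(replicate layout matching a typical manual-scoring campaign), intercept
0.150 foci/cell, slopes 12.518 (1 h) and 1.956 (24 h) foci/cell/Gy, and
φ = 60. Per-design-row substreams are spawned from the scenario seed, so
extending the design never perturbs earlier rows.

What the generator does *not* emulate: donor-level random effects beyond
an optional per-donor mean multiplier (used only for the power check of
the deviance test), scorer effects, partial-body exposure mixtures, and
any within-cell frequency-distribution structure (only totals are
modelled, as in the estimation framework itself). Passing coverage tests
therefore demonstrate correctness of the propagation under the assumed
moment structure, not robustness to systematic biases — which is exactly
what the reference-sample validation step exists for.

## Numerical and design choices

* Dispersion of a perfect (zero-residual) fit is 0; such a curve carries
  `phi=None` and downstream consumers fall back to the consensus value.
* The deviance test scales the Poisson deviance by the Pearson φ̂ (not a
  quasi-F statistic), keeping the arithmetic of the scaled χ² comparison.
* Yield-scale equivariance: scaling A, B, SEs and y\* by k leaves x\* and
  SE(x\*) unchanged only if φ is also scaled by k (the sampling term is a
  yield-scale variance); the tests assert this corrected statement.
* Display rounding is presentation-only; all serialized numbers keep full
  precision.
* Simulation sizes in the test suite: 2000 replicates for coverage
  checks, 500 for parameter recovery, 200 for dispersion recovery and
  donor power — chosen so Monte-Carlo error is small relative to the
  asserted bands.

## Known limitations

* Only two reference doses (0, r) are supported; more are rejected with a
  clear message rather than silently regressed.
* No Bayesian or weighted updating of a rejected curve with reference
  information; the reference curve replaces it outright.
* No model selection between linear and quadratic forms: the caller
  chooses, and the main estimation path is linear-only.
* The dispersion-recovery band [50, 70] for φ̂ on the default design is
  intrinsically tight: the sampling SD of φ̂ under the negative-binomial
  generator is ≈ 6, so ~9% of synthetic experiments legitimately fall
  outside.
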