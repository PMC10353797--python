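# Methods

## The model

The package fits Bayesian geo-additive multinomial logit models for a
trichotomous nutritional-status outcome y ∈ {underweight, normal,
overweight/obese} of reproductive-age women, with "normal" as the
reference category.  For woman i and non-reference category r,

    P[y_i = r] = exp(η_ir) / (1 + Σ_s exp(η_is)),

and the predictor η_ir is structured additively.  Six nested variants are
supported:

| variant | predictor |
|---------|-----------|
| M1 | u_i'β_r |
| M2 | u_i'β_r + f_r(z_i) |
| M3 | u_i'β_r + g_r(S_i) + h_r(S_i) |
| M4 | u_i'β_r + f_r(z_i) + g_r(S_i) |
| M5 | u_i'β_r + f_r(z_i) + h_r(S_i) |
| M6 | u_i'β_r + f_r(z_i) + g_r(S_i) + h_r(S_i) |

Here u_i are dummy-coded categorical covariates (residence, wealth
quintile, education, work status, water source, toilet facility,
electricity, newspaper/radio/TV exposure) with the reference levels fixed
to Rural / Poorest / No education / No / Unprotected / Unimproved / No /
No / No / No; z_i is age in years; S_i is the administrative division.

**Smooth age effect.**  f_r is a penalized B-spline: degree 3 on 20
equidistant knots spanning the observed age range.  We read "20
equidistant knots" as 20 knots spanning [z_min, z_max], i.e. m = 19
interior intervals and J = m + l = 22 basis functions — the common
structured-additive-regression convention; both the knot count and degree
are configurable because other conventions exist.  The prior on the
coefficients is a second-order random walk, ϑ_j = 2ϑ_{j−1} − ϑ_{j−2} +
e_j with e_j ~ N(0, σ_e²), equivalently an improper Gaussian with
precision K/σ_e² where K is the second-difference penalty (rank J − 2;
null space = linear trends in j).

**Spatial effects.**  g_r is an intrinsic CAR (GMRF) effect over the
division adjacency graph: conditionally, g(S_k) | rest ~ N(mean of
neighbours, δ/|N(k)|), jointly precision Q/δ with Q the graph Laplacian.
h_r is an exchangeable N(0, τ²) region effect.  Adjacent divisions
(sharing a boundary) are neighbours.  The bundled 7-division (2014-style)
and 8-division (2017-18-style, Mymensingh separate) graphs are plausible
hand-drawn approximations for testing; any graph can be supplied as an
edge list.

**Priors.**  β_r diffuse (∝ const); σ_e², δ, τ² inverse-gamma with shape
= rate = 0.001 (the conventional weakly-informative default, used for all
three since no distinct values are established for the spline variance).

## Inference

Each non-reference category r is updated conditionally on the other
category's predictor: the multinomial likelihood in category r's
parameters is then a binary logit with offset C_r = log(1 + exp(η_s)).
The default backend is exact Pólya–Gamma data augmentation: ω_i ~ PG(1,
η_ir − C_ir) turns the conditional into a Gaussian likelihood, and the
coefficient blocks (linear, spline, structured, unstructured) are drawn
block-by-block from their exact Gaussian full conditionals with prior
precisions 0, K/σ_e², Q/δ, I/τ².  Blockwise updates keep every
conditional proper: the level direction shared by the intercept, the
spline and the spatial effects is handled by recentring after every block
draw — the spline is centred by its design-weighted mean (the fitted
curve averages to zero over the sample ages), the spatial blocks by their
plain region mean — with the mean absorbed into the per-category
intercept, so η is unchanged to machine precision.  Variances get
conjugate inverse-gamma updates with effective dimensions J − 2 (spline),
rank(Q) (structured) and R (unstructured).

The PG(1, z) sampler is Devroye's exact alternating-series rejection
method, implemented in numba (the mixture of a truncated inverse-Gaussian
body and an exponential tail); its sample moments are tested against the
analytic mean tanh(z/2)/(2z) and variance.

A second backend (`augmentation="iwls_mh"`) replaces the PG step with an
independence Metropolis–Hastings update per block, proposing from the
iteratively-weighted-least-squares Gaussian approximation recomputed at
both the current and proposed points.  It targets the same posterior;
the test suite checks that the two backends give overlapping credible
intervals.

Chain defaults are 35,000 iterations, 5,000 burn-in, thinning 10 (3,000
retained draws).  Initialization is all-zero coefficients with variances
at 0.1; one seed drives separate per-category, variance and PG
sub-streams, so runs are bit-reproducible.  No automatic convergence
stopping is done; the deviance trace and MH acceptance rates are reported
and decisions are the user's.

**Prior-only mode** (`prior_only=True` with fixed variances) replaces the
data information with zero, drawing each penalized block from its prior
restricted to the row space of its precision (null-space directions
pinned at zero, flat-prior blocks held fixed).  This exposes the exact
Gibbs machinery to a closed-form check: the spline coefficients must then
be iid draws from the recentred pseudo-inverse covariance σ_e²·P K⁺ P'.

## Model comparison and summaries

DIC = D̄ + pD with D̄ the mean of the retained deviance draws (deviance
= −2 × multinomial log-likelihood) and pD = D̄ − D(θ̄) evaluated at the
posterior means of all blocks (Spiegelhalter's form, chosen because the
source material defines pD only verbally).  Models within 5 DIC of the
best are flagged as fitting equally well.  Effect summaries report
posterior means and central 95% intervals from empirical 2.5%/97.5%
quantiles (linear interpolation, no normal approximation); an effect is
"significant" when zero lies outside its interval.  We note that the
published table's footnote states the opposite convention ("significant …
as zero value is included"), which contradicts every reported result
pattern and is treated as a typesetting error.  Spatial effects are
exported per region with a three-class significance code (interval above
/ spanning / below zero), matching the usual map colouring; actual
choropleth rendering is out of scope.

## BMI classification and descriptives

WHO Asian cutoffs: underweight < 18.5, normal [18.5, 23), overweight
[23, 27.5), obese ≥ 27.5 kg/m²; the boundary convention is
left-closed/right-open (a BMI exactly at a cutpoint falls in the higher
class) and configurable, since prose definitions like "18.5 to 23.0" are
ambiguous at the boundaries.  The analysis collapses overweight and obese
into one class.  Eligibility filtering is flag-driven (pregnancy, recent
birth) followed by listwise deletion over the modelled covariates, with
an exclusion log counting each dropped record once under the first
matching reason (flags first, then covariates in the canonical order).
The "t-test for proportion" between survey rounds is implemented as the
pooled two-sample z-test; at these sample sizes the z and t references
are numerically indistinguishable.  Display percentages round half-up to
2 decimals; raw values are kept internally.

## The synthetic generator

The generator emulates a DHS-like cross-section: categorical covariates
drawn independently from the published per-level shares of the 2014 or
2017-18 round; age continuous-uniform on [15, 49] (the real age
distribution is not published; uniform maximizes spline-domain coverage
for recovery tests); division uniform over the graph unless region
weights are given; outcomes drawn from the multinomial logit above with
user-specified effects.  A BMI value is drawn uniformly inside the
interval matching the sampled category so the classification stage can be
exercised; it carries no additional signal.

Default "study condition" truths, fixed once: linear effects with the
published 2014-round magnitudes (e.g. +0.64 for richest-quintile
overweight/obesity, −1.339 for higher-education overweight/obesity);
intercepts −0.57 (underweight) and −0.49 (overweight/obese), calibrated
so implied prevalences sit near 18%/41%/41% under the 2014 margins;
sinusoidal age effects f(z) = 0.6·sin(2π(z−15)/34 + φ) with φ = 0
(underweight) and −π/2 (overweight/obese), one full period over the age
range so the curve has ≈ zero mean under uniform age; structured spatial
truth drawn once per dataset from the ICAR prior at δ = 0.15 and
recorded.  What the generator does **not** emulate: two-stage cluster
sampling, stratification and sampling weights (also ignored by the
model), covariate dependence (covariates are independent; a joint-sampler
hook exists), measurement error in height/weight, and the real spatial
population distribution.  Passing recovery tests therefore demonstrate
correctness of the fitting machinery under the stated model, not
robustness to DHS design features.

## Test problem sizes

Simulation-based checks run at sizes chosen to keep a routine test run
short while leaving the statistical conclusions clear: parameter-recovery
coverage uses 20 replicates of n = 4,000 with 7,000/2,000/5 chains
(coverage is assessed in aggregate across the 32 dummy coefficients, with
a per-coefficient floor to catch systematic misses); DIC selection sanity
uses 20 replicates each of n = 2,000 (null scenario, M1/M2/M4 at
1,000-iteration chains) and n = 4,000 (strong-spatial scenario, M1/M2 vs
M4/M5 at 800-iteration chains); consistency in n is checked at
n ∈ {1,000, 4,000}.  In the strong-spatial comparison the spatial
variants compared against M1/M2 are M4 and M5: M3 omits the smooth age
term, and on data containing a genuine age effect its DIC is dominated by
that omission regardless of spatial strength, so it is not a clean probe
of the spatial terms.

## Numerical choices and edge cases

Cholesky factorizations of full conditionals with `check_finite=False`;
the prior-only path falls back to an eigendecomposition for singular
precisions.  Multinomial probabilities are computed with max-shift
stabilization, so extreme predictors saturate without overflow.  Zero
predicted probability for an observed outcome makes the deviance +inf
rather than raising.  Ages outside the training knot range fail hard
during fitting (the penalty's interpretation depends on the grid) and can
be clamped only for prediction/export.  Regions with no neighbours are
rejected for structured effects by default (policy configurable to
pinning their effect at zero).  IWLS weights are clipped below at 1e-6.

## Known limitations

Identification of g versus h in M3/M6 comes entirely from their priors
(the classic convolution-model confounding); their sum is well identified
and DIC is unaffected, but individual g/h summaries in those variants mix
slowly.  The independence-IWLS backend can have low acceptance for very
large blocks.  DIC is the only comparison criterion implemented.  The
division adjacency presets are approximations; analyses of real data
should supply the official boundary-derived edge list.
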