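# Methods

## Data-generating processes

One simulated study is `m` mountains with per-mountain sample sizes
summing to `200·m`. Heights follow

    height_ij = (β₀ + b₀ᵢ) + (β₁ + b₁ᵢ)·T_ij + ε_ij,

`b₀ᵢ ~ N(0, σ²_b0)`, `b₁ᵢ ~ N(0, σ²_b1)` independent of each other
(scenario A fixes `b₁ᵢ = 0`), `ε_ij ~ N(0, σ²_e)`. Under the null all
population-level effects are 0; under the weak alternative
`β₀ = β₁ = 0.4` cm. Random-effect variances are 0.01 or 0.25 cm².

Constants the study design leaves open are fixed once as package
defaults:

- **Residual sd `σ_e = 1.0` cm.** This is the value under which the
  pooled regression that ignores the grouping variable shows the
  characteristic type I inflation of roughly 0.26 (variance 0.01) and
  0.78 (variance 0.25) predicted by the large-sample formula
  `2·Φ(−z_0.975/√(1 + n̄·σ²_b1/σ²_e))` with `n̄ = 200`. It is exposed as
  `ScenarioConfig.resid_sd`.
- **Temperature**: i.i.d. standard normal per plant, z-scored within each
  dataset. No spatial or transect structure is imposed.
- **Unbalance**: per-mountain shares drawn uniformly on [0.1, 0.9],
  normalized, rounded by largest remainder to the exact total, redrawn
  until every count lies in [40, 360]. Counts are redrawn every
  replicate. For the design sweep the constraint is instead "at least 3
  observations per level" and counts are part of the sampled design,
  fixed across that design point's replicates.
- **Seeds**: every replicate owns one `numpy` Generator seeded by
  `condition_seed + replicate_index` (condition seeds derive linearly
  from the master seed, kept below 2³¹). A zero variance consumes no
  random numbers, so scenario A is bit-identical to scenario B with
  `var_slope = 0` under the same seed, and results are invariant to
  execution order.

What the generator deliberately does not emulate: non-Gaussian responses,
correlated random intercepts and slopes in the *generating* process (only
tested model M11 estimates a correlation), spatial autocorrelation along
transects, measurement error in temperature. Passing tests therefore
speak to the statistical mechanics of the model comparison, not to
robustness against those real-data features.

## Mixed-model engine

The marginal model is `y ~ N(Xβ, σ²_e(I + ZΛΛ'Z'))` with Λ the relative
Cholesky factor of the random-effect covariance (scaled by σ²_e).
Uncorrelated specifications constrain Λ diagonal; the correlated model
(M11) uses a dense lower-triangular 2×2. For fixed θ (the free entries of
Λ), β and σ²_e have closed-form profile estimates, leaving a 1–3
parameter bounded optimization of

    −2ℓ_R(θ) = log|V*| + log|X'V*⁻¹X| + (n−p)(1 + log(2π r²/(n−p)))

(REML; the ML criterion drops the middle term and uses n). Groups are
independent and carry at most two random terms, so each evaluation uses
the Woodbury identity on per-group 2×2 blocks — O(m) small-matrix work
after a single pass over the data, about 50 µs per evaluation and 10–25 ms
per fit.

Numerical choices:

- **Optimizer**: L-BFGS-B with bounds (Λ diagonals ≥ 0) from five
  deterministic starts — θ = 0 (the boundary), two fixed interior points,
  a moment-based start from per-group OLS spreads, and their midpoint —
  followed by a central-difference polish (`ftol` 1e-14). Boundary optima
  are legitimate solutions, not failures; starting *at* the boundary
  guarantees they are reachable. Closed-form agreement with the balanced
  one-way ANOVA estimators is at 1e-6 relative or better.
- **Degenerate regions**: for extreme θ the whitened cross-product
  `X'V*⁻¹X` can underflow to singularity (at m = 2 the random terms span
  the fixed effects); the criterion returns a large finite value there so
  line searches retreat.
- **Singularity** is declared when a Λ diagonal falls below 1e-4 or an
  implied correlation exceeds 1 − 1e-4 in magnitude — the lme4
  convention.
- **Satterthwaite df**: `df = 2v²/(g'Ag)` with `v` the coefficient
  variance as a function of (θ, σ_e), `g` its central-difference gradient
  (step `1e-4·(1+|·|)`), and `A = 2H⁻¹` from the finite-difference
  Hessian of the deviance in the same parameters. df is clipped to
  [1, n−p]; an unusable curvature (non-invertible, or a non-positive
  quadratic form at boundary estimates) falls back to the residual df
  n − p with a logged warning — exactly the OLS limit the collapsed model
  occupies. Validated against lmerTest to ~1e-4 relative on interior
  *and* boundary fits.

## Fixed-effects engine

M2/M3/M7/M8 are ordinary least squares (via statsmodels) with classical
covariance `σ̂²(X'X)⁻¹`. M8's population-level slope is the average of the
m per-level slopes; its standard error comes from a parametric bootstrap:
B draws (default 10,000) of the coefficient vector from
`N(β̂, Cov(β̂))`, each averaged with equal weights 1/m (broad-sense
inference treats levels symmetrically) or optionally `n_i/n` weights for
unbalanced-design sensitivity. The p-value refers `estimate/se` to a
standard normal — the statistic is a smooth linear functional of the
coefficients. The bootstrap se converges to the closed form `√(w'Vw)` at
rate 1/√B; tests require 5% agreement at B = 10⁴.

## Replicate orchestration and aggregation

Each condition (scenario, m, variance, effect) simulates `n_reps`
datasets and fits every tested model of that scenario to the same data,
so model contrasts are paired. Mixed-model rejection rates are reported
under three policies: non-singular fits only, all fits, and the singular
stratum alone; fixed-effects models always use all datasets. Printed
"average" rates aggregate per-m rates within one variance setting and
policy; per-m curves are always retained. Rejection uses strict
`p < α` (ties have probability zero for continuous statistics), and every
rate carries its binomial Monte-Carlo standard error `√(r(1−r)/n)`.

Variance-component summaries count an estimate as "at zero" by the same
boundary criterion as the singularity flag, and report zero mass, mean
and median per term for all fits and the non-singular subset — the
truncation of the zero mass makes the non-singular mean an upward-biased
estimate of the generating variance, which the tests verify directly.

## Design sweep

Designs are sampled as: m uniform on {2..20}, one variance for both
random terms uniform on [1e-4, 4], total n = factor·m with factor uniform
on {10..500}, shares uniform on [0.1, 0.9] normalized and redrawn until
every level keeps ≥ 3 observations; the unbalance proxy is the largest
minus the smallest share. Per design, scenario-B data are simulated under
the null and the weak effect; the correct mixed model contributes rates
over non-singular fits (retrying up to `retry_factor` times the quota;
designs that cannot accumulate any non-singular fit — tiny variances at
few levels — are flagged and excluded), the per-level fixed-effects model
over all fits.

Rates are smoothed by an additive quantile regression at τ = 0.5: cubic
B-spline bases (10 knots per covariate, column-centered for
identifiability) with a second-difference penalty, fitted by iteratively
reweighted least squares on the pinball loss (weight `τ/|r|` or
`(1−τ)/|r|` with a floored residual), penalty weight chosen by 5-fold
cross-validated pinball loss from a fixed grid. A small ridge pins down
the exactly-null direction that column-centering a partition-of-unity
basis leaves in each block. τ and the knot count are configurable;
uncertainty bands and interaction smooths are out of scope.

## Problem sizes

Replicate counts default to 1000 per condition (2000 for the stratified
scenario-B study, so both strata are populated at every m) and the sweep
to 200 design points × 200 fits; the package's acceptance run and test
suite use these desk-scale sizes, which keep every Monte-Carlo standard
error below about 0.7 percentage points at a 5% rate while completing in
minutes on one CPU. Full-scale runs (5000 replicates, 1000 × 1000 sweep)
are a configuration change, not a code change.

## Known limitations

- The Kenward-Roger approximation is not implemented; all mixed-model
  p-values are Satterthwaite.
- Only one grouping factor, at most random intercept + slope; no crossed
  or nested structures, no GLMMs.
- The singular-fit stratum mixes qualitatively different boundaries
  (intercept-only, slope-only, full collapse); its aggregate rejection
  rate is therefore sensitive to the generating constants (σ_e, n̄) in a
  way the non-singular stratum is not.
- The bootstrap p-value uses a normal reference; at very small m a t
  reference would be more conservative.
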