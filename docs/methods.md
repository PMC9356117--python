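# Methods

## The problem

A randomized two-arm longitudinal trial is analysed with a constrained
longitudinal data analysis (cLDA) linear mixed model, and a historical
control arm from a comparable earlier study is available.  Simply pooling
the historical controls risks bias and type I error inflation when the
studies differ; ignoring them wastes information.  The package implements
*dynamic* borrowing, where the data decide how much historical information
enters the analysis, through the modified power prior (MPP) in its
conditional and marginal forms and through the commensurate prior, with
pooling and no borrowing as reference analyses.

## Data model

For subject *i* with outcomes at times *t*:

y_it = β0 + (covariates β) + β1·t + β2·trt_i·t + u_0i + u_1i·t + ε_it

with subject effects (u_0i, u_1i) ~ N(0, G), errors ε ~ N(0, σ²), no
treatment main effect (randomization fixes the baseline mean; cLDA), and
the treatment acting only through the treatment-by-time interaction β2,
the parameter tested.  The historical model is identical without the
interaction term.  Time is continuous with a linear trend; a
categorical-time variant is not implemented.  G is parameterized as SDs τ
and a correlation Ω, G = diag(τ) Ω diag(τ).

## Borrowing methods

* **No borrowing** — the cLDA model on current data only.
* **Pooling** — historical control subjects enter the likelihood at full
  weight (their interaction covariate is zero).
* **Marginal MPP** — the historical *marginal* likelihood (random effects
  integrated out) is raised to a power α ∈ [0, 1] with prior Beta(a, b)
  (uniform by default; Beta(1, 2) as a skeptical sensitivity option).  The
  power prior is normalized by the scaling constant
  c(α) = ∫ L0(θ)^α p0(θ) dθ, without which the likelihood principle is
  violated and the α posterior is distorted.
* **Conditional MPP** — the historical likelihood *given* the random
  effects is tempered.  Because a Gaussian density raised to α is again
  Gaussian with variance σ²/α (times a computable constant), the
  historical random effects can be integrated out analytically *after*
  tempering: the historical term becomes
  N(y₀; X₀βC, Z₀GZ₀' + (σ²/α) I) plus the constant
  ((1−α)m/2)·log(2πσ²) − (m/2)·log α per subject.  This sampler avoids
  the historical random effects entirely.  At equal α the conditional
  variant weights historical information more strongly than the marginal
  one (σ²/α inflation vs. α-downweighting of the whole precision), which
  is why it borrows more — and why it is the variant prone to type I
  inflation under heterogeneity.
* **Commensurate prior** — the historical arm keeps its own coefficients
  β0C, covariance G₀ and error variance σ0²; the current shared
  coefficients get a MVN prior centred at β0C whose covariance Σ_βC
  (SDs half-normal(0, 1), correlation LKJ(1)) is estimated and governs
  the flow of information.

## Priors

Unit-information g-prior N(0, g·σ²·(XᵀX)⁻¹) on the fixed effects with
g = number of observations in the *current* study ("auto").  The prior is
joint over (βC, β2) using the current-study design; where a model block
involves only the shared coefficients (the power-prior normalizer, Step 1
sampling) the exact marginal of that joint normal is used.  For the
commensurate model's historical coefficients the g-prior is built from the
historical design with g = historical observation count.  Random-effect
SDs: half-normal(0, 1).  Error SD: half-normal(0, 4).  Correlations:
LKJ(η = 1).  Power parameter: Beta(1, 1).

## Posterior computation

Every model here is linear-Gaussian in its fixed effects, which the
sampler exploits: a blocked Gibbs scheme draws the coefficient block
exactly from its multivariate-normal full conditional and updates the
remaining blocks by adaptive random-walk Metropolis on unconstrained
scales (log SDs, atanh correlations, logit α):

* coefficient blocks (β; and β0C in the commensurate model): exact
  conjugate draws — this is why the treatment-effect chain mixes almost
  ideally;
* covariance block (τ, Ω, σ): joint 4-dimensional adaptive random walk
  (Haario running covariance, Robbins–Monro step-size tuning toward a 0.30
  acceptance rate), three sub-steps per sweep; adaptation is frozen at the
  end of burn-in;
* power parameter: one-dimensional adaptive walk on logit(α) (five
  sub-steps per sweep) mixed with a 25% uniform independence proposal so
  well-separated modes of a bimodal α posterior can be crossed; chains
  start from dispersed random α values.  The acceptance target of the
  α walk is the `target_accept` setting — 0.44 by default (the standard
  optimal-scaling value for a scalar random walk) and elevated to 0.60 for
  the conditional MPP, whose α posterior can be bimodal under
  heterogeneity.  These replace gradient-sampler acceptance targets
  (0.8/0.95), which are not meaningful for a random-walk kernel.

Defaults: 4 chains × 2000 iterations, 1000 burn-in.  Subjects sharing a
visit-time pattern share the marginal covariance, so likelihoods and
weighted-least-squares blocks are computed with one Cholesky
factorization per pattern (numba-compiled kernels with numpy fallbacks).
Convergence is summarised by split-R̂ and bulk ESS (cross-checked against
arviz in the test suite); fits with R̂ ≥ 1.05 on the monitored parameters
(fixed effects and error variance) are flagged, and the study harness
excludes and counts them.

### The scaling constant (Step 1)

Thermodynamic integration: d log c/dα = E_{θ~π_α}[u(θ, α)] where π_α is
the α-tempered historical posterior and u is the α-derivative of the
tempered log-kernel — the historical marginal log-likelihood for the
marginal MPP; for the conditional MPP the analytic derivative

u_i = −(m/2)log(2πσ²) − m/(2α) + (σ²/2α²)(tr W⁻¹ − ‖W⁻¹r‖²),
W = Z₀GZ₀' + (σ²/α) I,

whose α→0 limit is the expected conditional log-likelihood under the
random-effects prior.  E[u] is estimated on a grid (default 0:0.02:1, one
chain of 100 iterations per node, warm-started from the previous node,
50-iteration node burn-in), integrated with the cumulative trapezoid rule
anchored at log c(0) = 0, and interpolated piecewise-linearly — on the
log c scale by default, with interpolation of c itself behind a flag —
during Step-2 sampling.  The α = 0 node is the prior itself and is
evaluated by direct prior sampling (2000 draws by default).

Two numerical choices matter:

* **Rao-Blackwellisation.**  The integrand is quadratic in the shared
  coefficients, whose full conditional is Gaussian, so its conditional
  expectation is available in closed form (integrand at the conditional
  mean minus half the trace of curvature × conditional covariance).  The
  grid uses this averaged integrand, removing the dominant Monte-Carlo
  noise at small α where the tempered posterior is prior-like.  With the
  covariance parameters held fixed the whole model is conjugate and the
  averaged integrand is exact, which provides the closed-form oracle used
  in the tests.
* **The first-interval boundary layer.**  With a diffuse prior,
  E_prior[ℓ0] at α = 0 is far below the tempered-posterior values, and the
  integrand rises steeply within α ≪ first grid step; the trapezoid rule
  therefore misestimates the first increment substantially.  Because that
  error is a *constant* offset of log c for every α beyond the first node,
  it cancels from the shape of the α posterior on (step, 1] and affects
  only the negligible-mass sliver below the first node.  The test suite
  accordingly validates grid *increments* beyond the first node against an
  importance-sampling oracle, and absolute values in the conjugate
  (fixed-covariance) setting.

### Flatness of the power-parameter posterior

On homogeneous data the α posterior typically tilts up toward full
borrowing with its histogram mode at 1, but the upper half of the
posterior is very flat: an exact conjugate calculation (covariances fixed
at truth) shows log-density differences of only a few tenths between
α = 0.5 and α = 1, with the sign varying across simulated datasets.  The
boundary-mode checks therefore use the median histogram mode across
several simulated pairs and a stochastic tolerance rather than demanding
the boundary bin for every dataset.

## Decision rule and operating characteristics

The treatment effect is significant when the equal-tailed 95% credible
interval of β2 excludes 0 (equal-tailed rather than HPD; the skew of the
posterior is negligible here and equal-tailed is the convention of the
surrounding software ecosystem).  The study harness fits all methods to
identical simulated pairs (replicate r uses base seed + r), enabling
McNemar comparisons of paired rejection indicators (exact binomial under
25 discordant pairs, continuity-corrected χ² otherwise).  Calibrated
power recalibrates each method's rejection threshold to the empirical 5%
quantile of the null posterior tail probabilities
p = 2·min(Pr(β2<0), Pr(β2>0)) — equivalent to adjusting the credible
level, but computed from stored tail probabilities.

## The simulator

One current two-arm trial (default 100 subjects/arm) plus one historical
control arm (100 subjects), six visits at times 0, 0.2, …, 1; generating
values: intercept 2, slope 1, β2 ∈ {0, 0.36}, subject-effect variances
0.25/0.25 (uncorrelated), error variance 1.  Between-study heterogeneity
enters through study-specific intercept/slope effects d_j drawn
independently for each study from N(0, diag(σd0², σd1²)) — an
exchangeable, not fixed-bias, model — with seven named levels from
(0, 0) ("No") to (0.16, 0.16) ("RIS+High").  What the generator does not
emulate: missing visits, dropout, baseline covariates, unequal sample
sizes, non-Gaussian outcomes; conclusions from passing tests are
correspondingly limited to the balanced Gaussian setting.

## Scale of the shipped test suite

The default test suite and acceptance script are sized for a single CPU:
the replicated operating-characteristics checks use 50 replicates per
truth value (100 in total for bias; the null and alternative studies use
disjoint seed ranges so they are independent), 2 chains × 800 iterations,
and a grid step of 0.1 with 50 iterations per node; the nominal-level
check uses 200 replicates with 2 × 600 chains; the boundary-mode and
acceptance-script fits use the full 0.02 grid with 4 chains × 4000
iterations, the extra draws stabilising the histogram mode of the
nearly-flat upper posterior of α.  All checks state 3×MC-SE
tolerances at the replication actually run.  The full-scale study
(500 replicates, all seven scenarios) is available through
`histborrow run-study --full-scale`.

## Known limitations

* The commensurate covariance Σ_βC estimates a full correlation only for
  the 2-coefficient (intercept, time) shared block; with additional
  covariates the links are independent (diagonal Σ_βC).
* One historical study only; no MAP prior; no GLMM outcomes; no borrowing
  of (co)variance parameters in the commensurate model.
* The power grid inherits the trapezoid-rule boundary-layer bias described
  above; it is intrinsic to grid-based path sampling started at a diffuse
  prior.
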