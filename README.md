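# histborrow

Dynamic borrowing of a historical control arm in Bayesian linear mixed
models for longitudinal randomized trials.

When a new two-arm trial has a comparable historical control arm
available, borrowing that information can increase power and precision —
but pooling it outright inflates the type I error whenever the studies
differ.  `histborrow` implements the *modified power prior* (MPP) for the
linear mixed model in both of its forms, together with the commensurate
prior and the pooling / no-borrowing reference analyses, plus the trial
simulator and operating-characteristics machinery needed to evaluate them.

## Model and methods

The analysis model is a constrained longitudinal data analysis (cLDA)
linear mixed model for subject *i* at time *t*:

```
y_it = β0 + β1·t + β2·trt_i·t + b_0i + b_1i·t + ε_it,
(b_0i, b_1i) ~ N(0, G),   ε_it ~ N(0, σ²)
```

with the baseline mean shared across arms (no treatment main effect) and
β2, the treatment-by-time interaction, as the tested treatment effect.
The historical control arm follows the same model without the interaction.

Writing L(θ|y) and L(θ|y₀) for the current and historical likelihoods,
the modified power prior gives the joint posterior

```
p(θ, α | y, y₀) ∝ L(θ|y) · L(θ|y₀)^α / c(α) · p₀(θ) · p₀(α),
c(α) = ∫ L(θ|y₀)^α p₀(θ) dθ,   α ∈ [0, 1]
```

where α = 0 ignores and α = 1 pools the historical data, and the scaling
constant c(α) — estimated by path sampling on a grid of powers and
interpolated — makes joint estimation of α coherent.  For a mixed model
the tempering can act on the *marginal* likelihood (random effects
integrated out: the **marginal MPP**) or on the *conditional* likelihood
given the random effects (the **conditional MPP**); in the Gaussian case
the conditional variant's historical random effects integrate out
analytically after tempering, leaving a marginal covariance
`Z G Zᵀ + (σ²/α) I`, so at equal α it borrows more.  The **commensurate
prior** instead gives the historical arm its own parameters and links the
shared coefficients through βC ~ MVN(β0C, Σ_βC) with the SDs of Σ_βC
estimated from the data.

Sampling is by blocked Gibbs: fixed effects are drawn exactly from their
Gaussian full conditionals, covariance parameters and α by adaptive
Metropolis (details in `docs/methods.md`).  The treatment effect is
declared significant when its equal-tailed 95% credible interval excludes
zero.

## Worked example

Simulate a trial pair with a modest between-study shift and a true
treatment effect of 0.36, then fit the marginal MPP and the
current-data-only analysis:

```
$ histborrow simulate --scenario "RI+Low" --effect 0.36 --seed 11 --out-dir demo
wrote demo/current.csv (1200 rows) and demo/historical.csv (600 rows)

$ histborrow fit --method mmpp --current demo/current.csv \
      --historical demo/historical.csv --seed 11 --out demo/mmpp
{
  "betaT_mean": 0.480072186056355,
  "betaT_sd": 0.13767821976085523,
  "ci95": [0.2056616729245676, 0.749593749480659],
  "significant": true
}

$ histborrow fit --method none --current demo/current.csv --seed 11 --out demo/none
{
  "betaT_mean": 0.45274109980003496,
  "betaT_sd": 0.15506551863522616,
  "ci95": [0.15464486202157718, 0.7621311349907505],
  "significant": true
}
```

Both analyses find a significant effect, but borrowing shrinks the
posterior SD of the treatment effect from 0.155 to 0.138 — the historical
controls sharpen the control-arm trajectory.  The power parameter's
posterior (in `demo/mmpp_summary.json`) has mean 0.61 and interquartile
range (0.42, 0.80): the data support substantial but not full borrowing,
consistent with the low simulated heterogeneity.  `demo/mmpp_grid.csv`
holds the path-sampled scaling-constant grid, and each output directory
contains a `manifest.json` for exact reproduction.

The same is available as a library, scikit-learn style:

```python
from histborrow import MarginalMPP, simulate_trial, ScenarioSpec

cur, hist = simulate_trial(ScenarioSpec.named("RI+Low", beta2=0.36), seed=11)
est = MarginalMPP(seed=11).fit(cur, hist)
result = est.treatment_effect()      # mean, SD, CI, significance, alpha summary
```

Replicated operating characteristics (type I error, power, calibrated
power, bias, posterior SD, MSE, with Monte-Carlo SEs):

```
histborrow run-study --scenarios "No,RIS+High" --methods none,pool,mmpp \
    --reps 100 --effects 0,0.36 --seed 1 --out study/
histborrow report study/
```

`--full-scale` switches to the full 500-replicate, 4×2000-iteration
configuration.

## Configuration

YAML/JSON config mirrors the `ModelConfig` dataclass:

```yaml
prior:
  g: auto              # g-prior scale; auto = current-study observation count
  re_sd_scale: 1.0     # half-normal scale for random-effect SDs
  err_sd_scale: 4.0    # half-normal scale for the error SD
  lkj_eta: 1.0
  alpha_prior: [1, 1]  # Beta prior on the power parameter; [1, 2] = skeptical
mcmc:
  chains: 4
  iterations: 2000
  burn_in: 1000
  target_accept: 0.44
  seed: 0
grid:
  step: 0.02           # power-grid spacing (51 nodes)
  iterations_per_node: 100
  node_burn_in: 50
```
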