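# Methods

## Model

The unit of analysis is the original–replication study pair. With
effect estimates θ̂ₒᵢ, θ̂ᵣᵢ and standard errors σₒᵢ, σᵣᵢ on a common
normal scale, the response is the difference Δ̂ᵢ = θ̂ₒᵢ − θ̂ᵣᵢ with known
squared SE vᵢ = σ²ₒᵢ + σ²ᵣᵢ (the two studies are independent). All
models are normal for Δᵢ and differ only in the variance:

| model | variance of Δᵢ | heterogeneity parameter |
|---|---|---|
| multiplicative, constant | vᵢ·φ | φ ≥ 1 (clamped) |
| additive, constant | vᵢ + τ² | τ² ≥ 0 |
| multiplicative, location-scale | vᵢ·exp(z′ᵢα) | per-pair φ̃ᵢ = exp(z′ᵢα) |
| additive, location-scale | vᵢ + exp(z′ᵢα′) | per-pair τ̃²ᵢ = exp(z′ᵢα′) |

with mean x′ᵢβ throughout (xᵢ includes an intercept; categorical
covariates are reference-coded, first declared level = reference).
The log link keeps every per-pair heterogeneity positive; for the
multiplicative flavor the model-implied log standard deviation is
ln σ_Δ̂ᵢ + z′ᵢα/2, i.e. the known SE is an offset in the scale
predictor.

Key assumptions: pairs are independent; both effect estimates are
approximately normal with known SEs; the multiplicative flavor assumes
one common true effect-size difference (variance inflation only),
while the additive flavor lets true differences vary across pairs.
Orientation (flipping pairs so the original effect is non-negative)
makes a positive pooled difference interpretable as shrinkage.

## Estimation

* **Constant multiplicative.** β̂ is inverse-variance weighted least
  squares (weights 1/vᵢ); φ̃ is the weighted residual sum of squares
  divided by n − p − 1 (the REML-type, df-corrected mean squared
  error) or by n under the `method="ml"` switch. Reporting clamps
  φ̃ at 1; the raw value is retained, and the likelihood is evaluated
  at the raw value. Coefficient covariance is φ̃₊·(X′WX)⁻¹ with the
  clamped φ̃₊, so under-dispersion never shrinks standard errors.
* **Constant additive.** τ² maximizes the restricted likelihood via a
  bounded 1-D search on ln(τ² + ε), ε = 1e−12, with the upper bracket
  widened (×4) until the optimum is interior; a lower-boundary
  solution reports τ² = 0. β̂ is GLS at τ̂².
* **Location-scale additive.** REML over α with β profiled out by
  GLS; Nelder-Mead followed by BFGS polishing, initialized from the
  location-only fit (α₀ = ln τ̂², floored at ln 1e−8, other
  coefficients 0), with up to 5 jittered restarts. Wald SEs for α come
  from the central-difference Hessian of the negative restricted
  log-likelihood at the optimum; SEs for β from (X′Σ⁻¹X)⁻¹.
* **Location-scale multiplicative.** Full ML (the flavor's constant
  special case is then the ML variance, matching the GAMLSS-style
  computational route for this model class): alternating sweeps of WLS
  for β given α and analytic-gradient BFGS for α given β, declared
  converged when successive log-likelihoods differ by < 1e−9. Wald SEs
  from the joint numeric Hessian over (β, α). Per-pair φ̃ᵢ is clamped
  at 1 when reported/evaluated, never inside the likelihood, so
  printed scale coefficients are the unconstrained optimum.

The restricted log-likelihood uses the reparametrization-invariant
convention (it includes both the −½ln|X′WX| and +½ln|X′X| terms), so
REML-based AICs are comparable across fixed-effect sets; it matches
the value reported by standard random-effects meta-regression software
exactly. Confidence intervals are Wald with standard-normal quantiles
(matching how such coefficient tables are conventionally printed), not
t.

Prediction interval for a new pair: Δ̂ ± z·√(τ̂² + se(Δ̂)²) (additive) or
Δ̂ ± z·√(φ̂·se²_new + se(Δ̂)²) (multiplicative; the new pair's own
difference SE must be supplied). The multiplicative form is this
package's documented choice — it treats the new pair's sampling
variance as inflated by φ̂ — since no canonical formula exists for that
flavor.

## Model selection

AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n with k = p + 2 (location-only)
or p + q + 2 (location-scale), counting post-expansion columns (a
3-level categorical contributes 2 to p). ℓ is the fit's own
likelihood: REML for additive fits and the constant multiplicative
fit, full ML for multiplicative location-scale fits — stages are
ranked internally, never across estimation methods. Comparing
REML-based criteria across different fixed-effect sets is defensible
only under the invariant REML convention above, which is why that
convention is the default; an ML alternative exists for the
multiplicative location fits.

Enumeration respects pairing constraints declared as
`CovariateMeta.requires`: a constrained covariate enters only together
with its companion, so each requires-pair contributes a factor 3
(neither / companion only / both) and each free covariate a factor 2
to the search-space size. Stage 2 re-enumerates location subsets
within the stage-1 winner's pool (forced covariates always retained)
crossed with scale subsets of the same pool; candidates move as whole
covariates (a categorical block enters or leaves together).
Tie-breaks are deterministic: smaller k first, then lexicographic
covariate names. A fit that fails to converge is recorded with
criterion +∞ and a warning rather than aborting the search.

## Synthetic data

The simulator draws from exactly the generative models above:
covariates and the two SEs first (each from its own named sub-stream
of the root seed, so adding a covariate never perturbs other draws),
then Δ̂ᵢ ~ N(x′ᵢβ, vᵢ·exp(z′ᵢα)) or N(x′ᵢβ, vᵢ + exp(z′ᵢα′)). The
difference is split into two effect estimates by drawing
θ̂ᵣᵢ ~ N(0, σ²ᵣᵢ) and setting θ̂ₒᵢ = Δ̂ᵢ + θ̂ᵣᵢ, so the difference-SE
identity vᵢ = σ²ₒᵢ + σ²ᵣᵢ holds by construction. True replication
effects default to 0 because every estimator in the package depends on
the data only through the differences. Configurations implying
per-pair φᵢ < 1 are allowed but warned about, so tests can exercise
the reporting clamp.

`make_case_study_like` emulates the *structure* of a real
psychology/economics replication project: 87 pairs (69 + 18 across two
project labels), nine continuous covariates including the original SE
(SEs bounded inside (0.04, 0.58)), five categorical covariates
including a 3-level discipline, two share→count pairing constraints,
and true parameters of realistic magnitude (pooled shrinkage ≈ 0.2
Fisher-z units, per-pair multiplicative heterogeneity driven by
language overlap and citation count). What it does **not** emulate:
publication-bias selection, correlated covariates (e.g. same-language
vs same-country), heavy-tailed effect distributions, or missing
values. Passing tests on this generator therefore validate estimator
correctness and calibration under the model, not robustness to the
messiness of real project data.

## Numerical choices and edge cases

* Fisher-z transform requires |r| < 1 and n > 3; se = 1/√(n−3).
* Zero original effects count as already positively oriented.
* Complete-case per fitted model: a pair is dropped only when a
  covariate actually in that model is missing, with a logged count.
* Rank-deficient design matrices raise an error naming the collinear
  columns (pivoted QR).
* Scale covariates are used untransformed and uncentered, so scale
  coefficients can be evaluated at raw covariate values.
* Standardized residuals divide by the model's fitted per-pair SD
  (clamped heterogeneity for constant/location multiplicative fits,
  raw for ML location-scale fits, where the likelihood's own variance
  is the honest reference).
* Exponents inside scale submodels are clipped at ±700 to avoid
  overflow during optimization.

## Known limitations

* No risk-of-bias adjustment, limit meta-analysis, many-lab
  ("one phenomenon, many studies") designs, or publication-bias
  simulation.
* No DerSimonian-Laird / Paule-Mandel τ² estimators (REML only) and no
  robust/sandwich or Knapp-Hartung standard errors.
* REML-based model selection across fixed-effect sets, while
  conventional in this literature, remains statistically contentious;
  results should be read as exploratory ranking, not hypothesis tests.
* Wald intervals for scale coefficients can undercover at small n
  (they are asymptotic); the coverage tests run at n = 800.
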