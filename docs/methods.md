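# Methods

## Scope and data flow

`bonecost` analyses a cross-sectional cohort of adults aged 40+ with
thoracic vertebral fracture status (Genant semi-quantitative grade; fracture
= grade ≥ 1, conservative fracture = grade ≥ 2), trabecular vertebral BMD
(mg/cm³), task-cessation indicators, self-reported cessation reasons and
anthropometrics, together with population-level age schedules (hunting and
fishing kcal/day, fishing return rate kcal/hr, fishing minutes/day, dietary
intake) and a survivorship curve. Fracture grading, schedule estimation and
demographic fieldwork are upstream of the package: grades and schedules are
consumed as data. A synthetic-data module supplies both inputs so the
pipeline is fully runnable and testable offline.

## Synthetic cohort generator

The generator is the package's definition of the study conditions, not a
tuning surface.

- **Ages** are uniform on [40, 90]. A uniform draw gives every decade enough
  mass for stratified checks; a real age pyramid is thinner above 70.
- **Fracture** is Bernoulli at 36% (men) and 19% (women). For women the
  individual risk is log-linear in standardized BMD,
  p = p₀·exp(β·z − β²/2) with β = log 0.49 per SD; the −β²/2 term keeps the
  marginal prevalence on target when z ~ N(0, 1). Risks are truncated at 1
  in the extreme low-BMD tail (see *Log-binomial boundary* below). Men's
  fracture is independent of age and BMD, matching the absence of such an
  association in the motivating cohort.
- **Grades** among the fractured are multinomial over {1, 2, 3} with
  probabilities (0.7, 0.2, 0.1) — mild fractures are the most common — and
  10% of unfractured vertebrae read as borderline grade 0.5.
- **BMD** is a linear age trend (−2 mg/cm³ per year) around a mean of
  160 mg/cm³ plus N(0, 35²) residual; `bmd_sd` is the residual SD, so the
  total cross-sectional SD (~45) also reflects the age trend.
- **Cessation** is drawn from the logistic model
  logit p = β₀ + β_age·age + β_frac·fracture + β_bmd·z. Default
  coefficients were calibrated once against the published age-band
  participation pattern: hunting (−14.0, 0.194/yr), fracture log-odds
  log 7.3, BMD log 0.62/SD; tree chopping (−12.5, 0.18, log 6.9, log 0.75);
  weaving (−8.0, 0.10, log 2.2, log 0.51); full-day walking (−6.0, 0.10,
  log 8.2, log 0.77). Hunting and tree chopping are asked of men only,
  weaving of women only, walking of both.
- **Reasons and anthropometrics**: among ceasers, each reason is an
  independent Bernoulli with mobility (hip/back) probabilities boosted by
  +0.3 under fracture and sensory/endurance reduced by 0.1; weight is
  normal by sex and decomposes exactly into fat and fat-free mass.
- One `numpy.random.Generator` per call, seeded explicitly.

What the generator does **not** emulate: longitudinal repeat exams,
household structure, seasonality, measurement error in grading, and any
fracture–BMD dependence in men. Passing tests therefore demonstrate that
the estimators recover known structure under these idealized conditions,
not that the field estimates themselves are unbiased.

## Descriptive layer

Prevalence intervals are Wald on the proportion scale
(p̂ ± z·√(p̂(1−p̂)/n)), clipped to [0, 1] and reported in integer percent
with half-away-from-zero rounding; Wilson is available via
`method="wilson"`. 2×2 tables use chi-square with Yates continuity
correction, falling back to Fisher's exact test whenever any expected cell
is below 5. The correction and threshold are conventional defaults and are
toggleable/explicit in the API.

Fracture-risk regression uses a binomial GLM with log link (coefficients
are log relative risks), BMD entered per sample SD with the SD stored on
the fit.

**Log-binomial boundary.** The log link does not bound fitted probabilities
below 1, and when a strong protective RR meets a moderate baseline risk the
MLE can sit on the μ = 1 boundary; there the RR is attenuated and the Wald
variance is unreliable. Fits flag this as `boundary`; fitted probabilities
*above* 1 clear the `converged` flag. The consistent alternative — a
Poisson working model with robust (HC1) variance — is available behind the
explicit `poisson_fallback=True` option and is never substituted silently.
At the default calibration (19% prevalence, RR ≈ 0.5/SD) the boundary case
is structural: such a risk surface cannot be log-linear over the whole BMD
range, which is the standard motivation for the robust-Poisson estimator.

## Cessation models

Logistic regressions are maximum likelihood (Newton/IRLS, relative
log-likelihood tolerance 1e−8, at most 100 iterations). Separation is
detected as any standardized covariate coefficient exceeding 15 in
magnitude (the intercept is excluded: with uncentred age it is legitimately
near −14) or non-finite standard errors; separated fits are flagged, not
penalized. Stepwise comparison fits age + fracture (+ sex for walking)
first, then adds BMD, reporting AIC = 2k − 2ℓ and deltas. Zero-variance
covariates are dropped from the design rather than left to make it
singular.

q-values are computed within a caller-defined family (by default the four
task models): Storey with fixed λ = 0.5,
π₀ = min(1, #{p > λ}/((1−λ)m)), q₍ᵢ₎ = min₍j≥i₎ π₀·m·p₍ⱼ₎/j; BH is the
same step-up with π₀ = 1. With a small family of uniformly strong signals
Storey's π₀ can reach 0 and all q-values collapse to 0; that is the
estimator's behaviour at λ = 0.5, not an error. The spline smoother of the
original estimator is out of scope.

The mediation check refits the cessation model with anthropometric
covariates. Because weight = fat mass + fat-free mass identically, the
default adjustment set is (fat_free_mass, fat_mass); passing all three
would be singular by construction.

## Loss calculus

Adjusted production at age x is P(x)·p_still(x; profile), with BMD profiles
expressed as SD offsets on the fit's stored SD scale. Return rates are
assumed identical across profiles, so losses arise solely from cessation
and are conservative in that sense. Numerical choices:

- `days_per_year = 365` (configurable); annualization beyond that is not
  modelled.
- Integer age grid, schedule values read as mid-year averages, no
  interpolation; off-grid ages are errors rather than silently
  extrapolated.
- Future values condition on survival to the start age (division by
  l(x)); the sum truncates at the last schedule age, with hunting
  production identically zero from the terminal hunting age (75 by
  default).
- `loss_profile` computes all start ages with one reverse cumulative sum of
  l(a)·production(a); tests verify it against the brute-force per-age sum
  to 1e−10 relative tolerance.

Energy conversions use 4 kcal/g protein and 9 kcal/g fat with
half-away-from-zero integer rounding; percent-of-reference uses the same
rounding.

## Offsets

Daily: additional fishing minutes = 60·loss/return-rate; the percent
increase compares expected (observed + additional) with observed minutes.
Cumulative: hours = future loss/return-rate; day-equivalents divide by the
fishing hours/day observed at the rate-basis age. Real time allocation
varies with age, so day-equivalents are an approximation tied to the basis
age — exact day conversions would need the full age-specific allocation of
the future years.

## Pipeline

`run_pipeline` chains generation/loading → descriptives → stepwise fits
with fracture-q-values → loss profiles (fracture, and fracture with ±1 SD
BMD) → offsets, writing `results.json` (sorted keys, no timestamps —
byte-identical across runs at a seed), `loss_profile.csv`, `offsets.csv`
and a stage log with wall times and the seed. Any stage failure aborts with
a stage-labelled error. Configuration is a flat YAML mapping onto
`PipelineConfig`; defaults are α = 0.05, Storey FDR, 365 days/year,
fracture threshold grade ≥ 1.

## Problem sizes in the test suite

Parameter-recovery checks use cohorts of 5,000 (point recovery) and 200
replicates of 500 (interval coverage, AIC behaviour); the moment-matching
check uses 10,000. These sizes put Monte-Carlo error well inside the
asserted bounds (3 binomial SEs; ±3 SEs on log-OR scale) while the whole
suite stays in the tens of seconds.

## Known limitations

- The generator's logistic and log-linear structures match the fitted
  models by construction; model misspecification is untested.
- Profile-likelihood intervals are not implemented (Wald only).
- Survivorship is a single schedule; the package does not distinguish
  men-only from population mortality beyond what the caller supplies.
- Figure-level curve reproduction from the motivating study is not possible
  without its unpublished production tables; the calibration run asserts
  the qualitative shape (loss rising to a peak near the early 60s, zero at
  the terminal hunting age) instead.
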