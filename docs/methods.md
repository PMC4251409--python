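# Methods

## Model and assumptions

Heart age `a` is treated as a latent per-subject parameter with prior
`a | x ~ N(x, σa²)`, `σa = 7.5` years by default (configurable). The value
is motivated by coronary-artery-calcium age adjustments to Framingham risk
scoring: an average swing of 4.5 risk points at ~2 years per point gives
±9 years at roughly the 12.5th/87.5th percentiles, and
`9 / Φ⁻¹(0.875) ≈ 7.8` years — close to 7.5. `grundy_age_adjustment()` and
`grundy_prior_scale()` expose these two computations.

Each ECG output is modelled as a quadratic trend in body age plus a linear
drift in the heart-age offset:

    y | x, a ~ N(β x̲ + θ (a − x), Λ),   x̲ = (1, x, x²)ᵀ.

Assumptions worth stating explicitly:

- the heart-age offset `a − x` is independent of the measurement noise;
- a subject's heart age is stable over one month, so test-retest pair
  differences are pure noise contrasts (`E(ddᵀ) = 2Λ`);
- the quadratic mean captures the age trend (the outputs were screened for
  slight non-linearity in age, hence degree 2 and a residual-variance
  divisor of exactly `n − 3`);
- models are gender-specific (1 = male, 2 = female) except `Λ`, which is
  shared because repeatability data are scarce; `fit_gender_model` accepts a
  precomputed `lambda_cov` to implement the sharing, or estimates it from
  pairs when a gender has enough of its own.

With a Normal prior and Normal likelihood the posterior is Normal; the
closed-form mean and SD are implemented in `predict_heart_age` (k outputs)
and `predict_heart_age_single` (scalar), and `posterior_density` evaluates
Bayes' rule numerically on a grid as an independent oracle.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| `sigma_a` | years | 7.5 | prior SD of heart age about body age |
| `beta` (k×3) | output units | fitted / published | quadratic age trend per output |
| `theta` (k) | output units / year | fitted / published | sensitivity to the heart-age offset |
| `lambda_cov` (k×k) | output units² | fitted / published | within-subject noise covariance |
| `gamma1`, `gamma2` (7) | — | published | logistic composite-score coefficients |

Published constants (θ̂, β̂ per gender, Λ̂⁻¹, γ₁, γ₂, σa) ship verbatim in
`src/heartage/data/published_model.json`; `load_published_model` inverts the
stored Λ̂⁻¹ to obtain `Λ`. For the published male model
`θᵀΛ⁻¹θ = 0.16656`, giving shrinkage weight `w ≈ 0.9036` and posterior SD
2.33 years.

## Degenerate and edge cases

- `σ̂ν² ≤ λ̂²` leaves the variance decomposition without a real root; `θ̂`
  is set to 0 with a logged warning. This is conservative: the output is
  treated as carrying no age signal and the prediction falls back to the
  prior mean (body age).
- `sgn(β̂₁)` at exactly zero slope is taken as +1 — a deterministic
  tie-break; `θ̂` is at or near 0 there regardless.
- A non-positive-definite `Λ̂` (possible for small m with k ≥ 2) falls back
  to its diagonal with a warning, matching the componentwise use of
  `λ̂_jj` in `θ` estimation; `on_nonpd="raise"` disables the fallback. For
  k = 1 a zero `λ̂²` is returned as-is (identical repeats).
- Quadratic fits require n ≥ 4 and at least three distinct ages (full-rank
  design); violations raise with the offending columns named.
- All angles entering trig functions are degrees, converted by π/180; the
  `log` in the composite features is the natural logarithm. Raw-variable
  units are taken as provided and must match those used when the
  coefficients were fitted; the CLI performs no unit conversion and rejects
  records with missing or non-positive log arguments rather than imputing.

## Numerical choices

- The grid oracle spans at least `x ± 5σa` (tests use ±8σa, 6–8k points),
  normalises by trapezoidal quadrature, and rejects grids whose edge density
  exceeds 1e-6 of the peak. Closed form and grid mean agree to < 1e-6 years
  across randomized instances with k ∈ {1, 2, 3}.
- The logistic refit of composite coefficients uses Newton/IRLS with
  tolerance 1e-8 and at most 100 iterations; perfect separation (no finite
  MLE) raises `SeparationError` suggesting penalization.
- Every random routine takes an explicit seed; cohorts record it in their
  metadata, and multi-experiment drivers derive child seeds from a
  `SeedSequence` so runs are reproducible end to end.

## Synthetic cohorts: what they do and do not emulate

`simulate_cohort` draws `x ~ Uniform(age_low, age_high)` (or uniform within
coarse age bands when a scenario prescribes band percentages),
`a = x + δ` with `δ ~ N(delta_mean, delta_sd²)`, and
`y = β x̲ + θ δ + ε`, `ε ~ N(0, Λ)` — exactly the generative model the
estimator assumes. `simulate_repeats` reuses one latent `(x, a)` per pair.
The group scenarios reproduce the study-group composition (sizes 545 / 183 /
48 / 221 / 441; female fractions and age-band percentages per group) of the
cohorts the estimator was originally evaluated on. Healthy groups use
`delta_mean = 0`; the offsets for athletes (+2 y), risk-factor subjects
(+8 y) and diseased subjects (+18 y) are calibration defaults chosen to land
near the qualitative orderings reported for such groups (slightly more than
half, about three-quarters, nearly all predicted older than body age) — they
are configurable, not claims.

Because simulation operates at the composite-output level with exactly the
assumed model, passing tests demonstrate internal consistency (correct
formulas, unbiased estimators, calibrated shrinkage) — not that real ECGs
follow a quadratic-plus-drift Normal model, nor anything about raw-waveform
processing, which is upstream of this package. Real-data features the
simulator omits: non-Normal noise, age-dependent Λ, output nonlinearity in
`a − x`, and selection effects in cohort assembly.

## Evaluation diagnostics

- `fraction_above`: proportion with `â > x` (ties count as not above) — the
  group-level summary used for real cohorts.
- `shrinkage_slope`: OLS slope of `â − x` on the true offset `a − x`
  (synthetic data only); approaches `w` for a cohort generated from the
  prediction model (≈ 0.9036 for the published male model, verified at
  n = 100,000 within 0.005).
- `compare_gs_ngs`: paired mean difference of pooled-model vs
  gender-specific predictions with a paired-t interval. Note the interval
  conditions on the fitted models: it measures whether the two fitted
  models differ for these subjects, not sampling error of the fits, so
  under a no-gender-effect generative process per-seed intervals sit off
  zero by fit noise while the across-seed mean difference is centred on
  zero with mirrored signs between genders (this is what the tests assert).
- `recovery_experiment`: simulate → refit → report bias/RMSE per parameter.
  At the study-size conditions (545 subjects per gender, 15 repeat pairs,
  100 replicates) β̂ is unbiased within Monte-Carlo error and θ̂ recovers
  truth within a few percent.

## Problem sizes

Default test and reproduction runs use the study-condition sizes: cohorts of
545 per gender, 15 repeated-measure pairs, 100 recovery replicates, 2,000
replicates for noise-estimator unbiasedness, 200 replicates for the
healthy-cohort fraction, and 100,000 subjects for the shrinkage slope. The
whole suite plus the reproduction script completes in well under a minute on
one CPU.

## Known limitations

- The posterior SD is exposed although the original analysis reported only
  the mean; it follows directly from the Normal posterior.
- No Bayes-factor comparison of gender-specific vs pooled models and no
  ROC-style disease-detection analysis: the estimator is designed for
  healthy adults (≥ 20 years), and applications to risk-factor, disease or
  athlete groups are exploratory.
- Composite-score refitting assumes the two scores are fitted in separate
  logistic regressions of disease status on the respective feature vectors.
- No MCMC and no hierarchical extensions; the posterior is closed-form.
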