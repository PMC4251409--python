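# heartage

Bayesian estimation of cardiac age ("heart age") from resting 12-lead ECG
outputs, for biostatisticians and ECG researchers who want a personalized,
physiology-based alternative to questionnaire-style heart-age calculators.

## The model

Heart age `a` is a latent quantity: only body age `x` (years, ≥ 20) and a
vector of `k` ECG-derived outputs `y` are observed. The estimator combines

- a Normal prior centred at body age, `a | x ~ N(x, σa²)` with `σa = 7.5`
  years (consistent with coronary-artery-calcium-based age adjustments to
  the Framingham risk model, which imply a spread of about ±9 years, i.e.
  an SD of roughly 7.8 years);
- a likelihood in which each output follows a quadratic trend in body age
  plus a drift proportional to the heart-age offset:
  `y | x, a ~ N(β x̲ + θ (a − x), Λ)` with `x̲ = (1, x, x²)ᵀ`.

The posterior is Normal, with mean

    â = x + θᵀΛ⁻¹(y − β x̲) / (1/σa² + θᵀΛ⁻¹θ)

and SD `(1/σa² + θᵀΛ⁻¹θ)^(−1/2)`. All parameters are estimable from data:

- `β` and the total residual variance `σν²` per output by quadratic OLS of
  the output on body age (`σν² = SSE/(n−3)`);
- `Λ` from month-apart repeated ECGs, which share their latent heart age,
  so the pair difference `d` satisfies `E(ddᵀ) = 2Λ`:
  `Λ̂ = (1/2m) Σ ddᵀ`;
- `θ_j = sgn(β₁ⱼ)·√(σνⱼ² − λⱼⱼ²)/σa` from the variance decomposition
  `σν² = θ²σa² + λ²`.

Models are fitted per gender (1 = male, 2 = female; hearts age differently),
with `Λ` shared. The two standard ECG outputs are logistic-regression
composites of advanced ECG variables (T-wave axis, P-wave duration,
high-frequency QRS voltages, QT variability indices, spatial QRS-T angle,
…); published coefficient vectors and fitted model constants ship with the
package as a JSON resource, and a synthetic-cohort simulator generates data
from the model above so that every stage — fitting, prediction, evaluation —
is testable without any ECG database.

## Worked example

```python
import heartage

male, coeffs = heartage.load_published_model("M")

# a 50-year-old man whose ECG outputs correspond to a latent heart age of 60
x = 50.0
y = male.mean_outputs(x) + male.theta * 10.0
pred = heartage.predict_heart_age(x, y, male)
print(round(pred.a_hat, 3), round(pred.posterior_sd, 3),
      round(male.shrinkage_weight, 4))
```

prints

```
59.036 2.329 0.9036
```

The posterior mean pulls the 10-year offset back toward body age by the
shrinkage weight `w = θᵀΛ⁻¹θ / (1/σa² + θᵀΛ⁻¹θ) ≈ 0.9036`: the ECG carries
enough information to recover ~90% of a true heart-age offset, and the
posterior SD drops from the prior 7.5 years to 2.33 years.

The same pipeline is scriptable from the shell:

```sh
heartage simulate --scenario HNA-train --seed 3 --out-dir run/
heartage fit --subjects run/cohort.csv --repeats run/repeats.csv --out run/model.json
heartage predict --subjects run/cohort.csv --model run/model.json --out run/preds.csv
heartage evaluate --predictions run/preds.csv --truth run/cohort.csv --out run/report.json
```

Subjects files may carry either precomputed outputs (`y1`, `y2`) or raw
advanced-ECG variables (`taxis_deg`, `pd`, `frqrsmax_deg`, `hfp`, `rmssum`,
`spatialjt`, `iiqtvi`, `unexqtvi`, `qrsaxis_deg`, `meanqrst_deg`, `idr`),
which are transformed with the published composite coefficients.

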