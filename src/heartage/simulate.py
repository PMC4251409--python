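"""Synthetic cohorts drawn from the heart-age generative model.

Subjects are generated at the composite-output level, which is the level the
estimator consumes: body age x ~ Uniform (or uniform within coarse age
bands), a latent heart-age offset delta ~ N(delta_mean, delta_sd^2) so
a = x + delta, and outputs

    y = beta @ (1, x, x^2) + theta * delta + eps,   eps ~ N(0, Lambda).

Repeated-measure pairs share one latent (x, a) and differ only in two
independent noise draws, so their difference has covariance 2 Lambda — the
property the Lambda estimator relies on.  The four group scenarios mimic the
published cohort composition (sizes, gender mix, age bands) of healthy
non-athletes, athletes, risk-factor subjects and diseased subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import load_published_model
from .model import GenderModel, RepeatedMeasurePair

__all__ = [
    "CohortConfig",
    "GROUP_SCENARIOS",
    "simulate_cohort",
    "simulate_repeats",
    "make_group_scenarios",
]

# age bands used in the published cohort description (20-40, 41-60, 60+)
AgeBands = tuple[tuple[tuple[float, float], float], ...]


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one simulated cohort.

    delta_mean / delta_sd parameterise the heart-age offset a - x in years:
    0 / 7.5 for healthy subjects, positive delta_mean for groups whose
    hearts age faster.  gender_mix is the fraction of males.  age_bands, if
    given, replaces the Uniform(age_low, age_high) body-age draw with a
    band-then-uniform-within-band draw (band, probability pairs).
    """

    n: int
    age_low: float = 20.0
    age_high: float = 80.0
    gender_mix: float = 0.5
    delta_mean: float = 0.0
    delta_sd: float = 7.5
    group_label: str = "HNA"
    seed: int | None = None
    age_bands: AgeBands | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_low < 20:
            raise ValueError("age_low must be >= 20 (model domain)")
        if not 0 <= self.gender_mix <= 1:
            raise ValueError("gender_mix must be in [0, 1]")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")
        if self.age_bands is not None:
            probs = [p for _, p in self.age_bands]
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("age_bands probabilities must sum to 1")


def _draw_ages(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.age_bands is None:
        return rng.uniform(cfg.age_low, cfg.age_high, size=n)
    bands = [b for b, _ in cfg.age_bands]
    probs = np.array([p for _, p in cfg.age_bands])
    idx = rng.choice(len(bands), size=n, p=probs)
    lo = np.array([bands[i][0] for i in idx])
    hi = np.array([bands[i][1] for i in idx])
    return lo + rng.uniform(size=n) * (hi - lo)


def simulate_cohort(
    config: CohortConfig,
    model_by_gender: dict[int, GenderModel],
) -> pd.DataFrame:
    """Draw one cohort; returns a tidy frame with the true latent ages.

    Columns: id, gender (1/2), age (body age), group, one column per model
    output (y1, y2, ...), a_true, delta_true, seed.  Reproducible: one
    explicitly seeded random stream per cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    genders = np.where(rng.uniform(size=n) < config.gender_mix, 1, 2)
    for g in np.unique(genders):
        if int(g) not in model_by_gender:
            raise ValueError(f"no model supplied for gender {g}")
    x = _draw_ages(config, rng, n)
    delta = config.delta_mean + config.delta_sd * rng.standard_normal(n)
    any_model = next(iter(model_by_gender.values()))
    k = any_model.k
    ids = any_model.output_ids or tuple(f"y{j + 1}" for j in range(k))
    X = np.column_stack([np.ones(n), x, x * x])
    Y = np.empty((n, k))
    for g in sorted(model_by_gender):  # fixed order keeps the draw reproducible
        model = model_by_gender[g]
        mask = genders == g
        ng = int(mask.sum())
        if ng == 0:
            continue
        chol = np.linalg.cholesky(model.lambda_cov)
        eps = rng.standard_normal((ng, k)) @ chol.T
        Y[mask] = X[mask] @ model.beta.T + np.outer(delta[mask], model.theta) + eps
    frame = pd.DataFrame({
        "id": [f"{config.group_label}-{i:05d}" for i in range(n)],
        "gender": genders,
        "age": x,
        "group": config.group_label,
    })
    for j, name in enumerate(ids):
        frame[name] = Y[:, j]
    frame["a_true"] = x + delta
    frame["delta_true"] = delta
    frame.attrs["seed"] = config.seed
    frame.attrs["config"] = config
    return frame


def simulate_repeats(
    model: GenderModel,
    m: int,
    seed: int | None = None,
    delta_sd: float | None = None,
) -> list[RepeatedMeasurePair]:
    """m test-retest pairs: each shares one latent (x, a), so the pair
    difference is a pure noise contrast with E(d d') = 2 Lambda."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    sd = model.prior.sigma_a if delta_sd is None else delta_sd
    chol = np.linalg.cholesky(model.lambda_cov)
    pairs = []
    for i in range(m):
        x = rng.uniform(20.0, 80.0)
        delta = sd * rng.standard_normal()
        mu = model.mean_outputs(x) + model.theta * delta
        e1 = chol @ rng.standard_normal(model.k)
        e2 = chol @ rng.standard_normal(model.k)
        pairs.append(RepeatedMeasurePair(subject_id=f"rep-{i:03d}",
                                         y_first=mu + e1, y_second=mu + e2))
    return pairs


# --------------------------------------------------------------------------
# group scenarios
# --------------------------------------------------------------------------

_BANDS = ((20.0, 40.0), (41.0, 60.0), (60.0, 80.0))


def _bands(p1: float, p2: float, p3: float) -> AgeBands:
    return tuple(zip(_BANDS, (p1, p2, p3)))


#: Scenario templates mirroring the published cohort composition: sizes,
#: female fractions and coarse age-band percentages per group.  The
#: heart-age offset means for ATH/RFS/DIS are calibration defaults (the
#: source cohorts give only qualitative statements), override as needed.
GROUP_SCENARIOS: dict[str, CohortConfig] = {
    "HNA-train": CohortConfig(n=545, gender_mix=0.59, delta_mean=0.0,
                              group_label="HNA", age_bands=_bands(0.56, 0.36, 0.08)),
    "HNA-test": CohortConfig(n=183, gender_mix=0.57, delta_mean=0.0,
                             group_label="HNA", age_bands=_bands(0.55, 0.36, 0.09)),
    "ATH": CohortConfig(n=48, gender_mix=0.62, delta_mean=2.0,
                        group_label="ATH", age_bands=_bands(0.92, 0.06, 0.02)),
    "RFS": CohortConfig(n=221, gender_mix=0.53, delta_mean=8.0,
                        group_label="RFS", age_bands=_bands(0.10, 0.59, 0.31)),
    "DIS": CohortConfig(n=441, gender_mix=0.66, delta_mean=18.0,
                        group_label="DIS", age_bands=_bands(0.07, 0.50, 0.43)),
}


def make_group_scenarios(
    seed: int | None = None,
    model_by_gender: dict[int, GenderModel] | None = None,
    delta_means: dict[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate all five group cohorts (HNA train/test, ATH, RFS, DIS).

    Uses the published gender models unless ``model_by_gender`` is given;
    ``delta_means`` overrides the per-scenario offset means.
    """
    if model_by_gender is None:
        model_by_gender = {g: load_published_model(g)[0] for g in (1, 2)}
    ss = np.random.SeedSequence(seed)
    out: dict[str, pd.DataFrame] = {}
    for (name, cfg), child in zip(GROUP_SCENARIOS.items(), ss.spawn(len(GROUP_SCENARIOS))):
        if delta_means and name in delta_means:
            cfg = replace(cfg, delta_mean=delta_means[name])
        cfg = replace(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        out[name] = simulate_cohort(cfg, model_by_gender)
    return out
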