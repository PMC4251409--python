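"""Estimator diagnostics: group summaries, shrinkage, recovery, gender effects.

On synthetic cohorts the true latent heart age is known, which enables
diagnostics unavailable on real data: the shrinkage slope (how much of a
true heart-age offset the posterior mean recovers, expected to approach
w = theta' Lambda^-1 theta / (1/sigma_a^2 + theta' Lambda^-1 theta)) and
parameter-recovery reports.  fraction_above mirrors the group-level summary
used for real cohorts: the proportion of subjects whose predicted heart age
exceeds their body age.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .model import (
    GenderModel,
    HeartAgePrediction,
    PriorSpec,
    RepeatedMeasurePair,
    fit_gender_model,
    predict_cohort,
)

__all__ = [
    "RecoveryReport",
    "fraction_above",
    "shrinkage_slope",
    "compare_gs_ngs",
    "recovery_experiment",
]


@dataclass(frozen=True)
class RecoveryReport:
    """Monte-Carlo recovery summary for one scalar parameter."""

    parameter: str
    truth: float
    estimate_mean: float
    bias: float
    rmse: float
    n_replicates: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.rmse < abs(self.bias) - 1e-12:
            raise ValueError("RMSE cannot be smaller than |bias|")

    def to_dict(self) -> dict:
        return asdict(self)


def _extract_xy(predictions) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(predictions, pd.DataFrame):
        return (predictions["body_age"].to_numpy(float),
                predictions["heart_age"].to_numpy(float))
    preds = list(predictions)
    if preds and isinstance(preds[0], HeartAgePrediction):
        return (np.array([p.x for p in preds]), np.array([p.a_hat for p in preds]))
    arr = np.asarray(preds, dtype=float)
    return arr[:, 0], arr[:, 1]


def fraction_above(predictions) -> float:
    """Proportion of subjects with predicted heart age strictly above body
    age; ties count as not-above.  Accepts a predictions frame (columns
    body_age, heart_age), a sequence of HeartAgePrediction, or (x, a_hat)
    rows."""
    x, a_hat = _extract_xy(predictions)
    if x.size == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean(a_hat > x))


def shrinkage_slope(predictions: pd.DataFrame) -> float:
    """OLS slope of (a_hat - x) on the true offset (a_true - x).

    Requires synthetic data (a_true column).  Equals the shrinkage weight w
    in expectation for a cohort generated from the prediction model.
    """
    x = predictions["body_age"].to_numpy(float)
    a_hat = predictions["heart_age"].to_numpy(float)
    a_true = predictions["a_true"].to_numpy(float)
    t = a_true - x
    if np.ptp(t) == 0:
        raise ValueError("true offsets a_true - x have zero variance; slope undefined")
    slope, _ = np.polyfit(t, a_hat - x, 1)
    return float(slope)


def compare_gs_ngs(
    cohort: pd.DataFrame,
    pairs: Sequence[RepeatedMeasurePair],
    prior: PriorSpec | None = None,
    output_ids: Sequence[str] = ("y1", "y2"),
    confidence: float = 0.95,
) -> dict[int, dict]:
    """Gender-specific (GS) vs pooled, non-gender-specific (NGS) comparison.

    Both model families are fitted on the same cohort (Lambda shared, from
    ``pairs``); predictions are paired per subject and the per-gender mean
    difference NGS - GS is reported with a paired-t confidence interval.
    When the generating process differs by gender, the pooled model is
    biased in opposite directions for the two genders.
    """
    prior = prior or PriorSpec()
    genders = cohort["gender"].to_numpy(int)
    if np.unique(genders).size < 2:
        raise ValueError("cohort must contain both genders")
    ids = list(output_ids)
    Y = cohort[ids].to_numpy(float)
    x = cohort["age"].to_numpy(float)
    gs = {
        g: fit_gender_model(x[genders == g], Y[genders == g].T, pairs,
                            gender=g, prior=prior, output_ids=ids)
        for g in (1, 2)
    }
    ngs = fit_gender_model(x, Y.T, pairs, gender=0, prior=prior, output_ids=ids)
    out: dict[int, dict] = {}
    for g in (1, 2):
        mask = genders == g
        a_gs = predict_cohort(x[mask], Y[mask], gs[g])
        a_ngs = predict_cohort(x[mask], Y[mask], ngs)
        diff = a_ngs - a_gs
        n = diff.size
        mean = float(diff.mean())
        if n > 1 and diff.std(ddof=1) > 0:
            lo, hi = scipy.stats.t.interval(
                confidence, n - 1, loc=mean, scale=diff.std(ddof=1) / np.sqrt(n))
        else:
            lo = hi = mean
        out[g] = {"mean_diff": mean, "ci_low": float(lo), "ci_high": float(hi), "n": n}
    return out


def recovery_experiment(
    truth_by_gender: dict[int, GenderModel],
    n_per_gender: int = 545,
    m_pairs: int = 15,
    n_replicates: int = 100,
    seed: int | None = None,
) -> list[RecoveryReport]:
    """Full-pipeline parameter recovery on simulated cohorts.

    Per replicate: simulate a cohort of ``n_per_gender`` subjects per gender
    from the truth models plus ``m_pairs`` repeated measures, refit beta,
    Lambda and theta, and accumulate the estimates.  Returns one report per
    scalar parameter (beta entries and theta entries, per gender).
    """
    from .simulate import CohortConfig, simulate_cohort, simulate_repeats

    ss = np.random.SeedSequence(seed)
    genders = sorted(truth_by_gender)
    any_model = truth_by_gender[genders[0]]
    k = any_model.k
    est_beta = {g: [] for g in genders}
    est_theta = {g: [] for g in genders}
    for child in ss.spawn(n_replicates):
        s1, s2 = child.spawn(2)
        cfg = CohortConfig(n=n_per_gender * len(genders),
                           seed=int(s1.generate_state(1)[0] % (2**31)))
        cohort = simulate_cohort(cfg, truth_by_gender)
        # Lambda is shared: one repeatability sample per replicate
        pairs = simulate_repeats(any_model, m_pairs,
                                 seed=int(s2.generate_state(1)[0] % (2**31)))
        lam = None
        for g in genders:
            sub = cohort[cohort["gender"] == g]
            ids = any_model.output_ids or tuple(f"y{j+1}" for j in range(k))
            fitted = fit_gender_model(
                sub["age"].to_numpy(), sub[list(ids)].to_numpy().T, pairs,
                gender=g, prior=any_model.prior, output_ids=ids,
                lambda_cov=lam)
            lam = fitted.lambda_cov
            est_beta[g].append(fitted.beta.copy())
            est_theta[g].append(fitted.theta.copy())
    reports: list[RecoveryReport] = []
    for g in genders:
        truth = truth_by_gender[g]
        B = np.stack(est_beta[g])   # (reps, k, 3)
        T = np.stack(est_theta[g])  # (reps, k)
        for j in range(k):
            for c, cname in enumerate(("b0", "b1", "b2")):
                tr = float(truth.beta[j, c])
                est = B[:, j, c]
                reports.append(RecoveryReport(
                    parameter=f"gender{g}.y{j+1}.{cname}", truth=tr,
                    estimate_mean=float(est.mean()),
                    bias=float(est.mean() - tr),
                    rmse=float(np.sqrt(np.mean((est - tr) ** 2))),
                    n_replicates=n_replicates, seed=seed))
            tr = float(truth.theta[j])
            est = T[:, j]
            reports.append(RecoveryReport(
                parameter=f"gender{g}.y{j+1}.theta", truth=tr,
                estimate_mean=float(est.mean()),
                bias=float(est.mean() - tr),
                rmse=float(np.sqrt(np.mean((est - tr) ** 2))),
                n_replicates=n_replicates, seed=seed))
    return reports
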