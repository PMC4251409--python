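"""Bayesian heart-age model: prior, regression/variance estimators, posterior.

The estimand is a subject's latent "heart age" ``a`` given body age ``x``
(years) and a vector of k ECG-derived outputs ``y``.  The model is

* prior:        a | x            ~  N(x, sigma_a^2)            (sigma_a = 7.5 y)
* likelihood:   y | x, a         ~  N(beta @ [1, x, x^2] + theta * (a - x), Lambda)

where ``beta`` (k x 3) captures the quadratic mean trend of each output in
body age, ``theta`` (k-vector) is the per-output sensitivity to the
heart-age offset a - x, and ``Lambda`` (k x k) is the within-subject
measurement-noise covariance.  The posterior for ``a`` is Normal with mean

    a_hat = x + (theta' Lambda^-1 (y - beta x_)) / (1/sigma_a^2 + theta' Lambda^-1 theta)

and variance (1/sigma_a^2 + theta' Lambda^-1 theta)^-1, with
x_ = (1, x, x^2).

Parameters are estimable from cohort data: ``beta`` and the total residual
variance sigma_nu^2 per output by quadratic OLS on body age; ``Lambda`` from
month-apart repeated measurements (test-retest pairs, which share the latent
heart age, so E(d d') = 2 Lambda for the pair difference d); and theta by the
variance decomposition sigma_nu^2 = theta^2 sigma_a^2 + lambda^2.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger("heartage")

__all__ = [
    "PriorSpec",
    "AgeRegressionFit",
    "GenderModel",
    "RepeatedMeasurePair",
    "HeartAgePrediction",
    "grundy_age_adjustment",
    "grundy_prior_scale",
    "fit_age_regression",
    "estimate_lambda",
    "estimate_theta",
    "fit_gender_model",
    "predict_heart_age_single",
    "predict_heart_age",
    "predict_cohort",
    "posterior_density",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

DEFAULT_SIGMA_A = 7.5  # years; prior SD of heart age around body age

#: gender codes used throughout: 1 = male, 2 = female ("M"/"F" accepted at IO)
MALE, FEMALE = 1, 2


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Normal prior on heart age, centred at body age.

    sigma_a : prior standard deviation in years (default 7.5).
    """

    sigma_a: float = DEFAULT_SIGMA_A

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_a) or self.sigma_a <= 0:
            raise ValueError(f"sigma_a must be positive, got {self.sigma_a}")

    @property
    def sigma_a2(self) -> float:
        return self.sigma_a**2


@dataclass(frozen=True)
class AgeRegressionFit:
    """Quadratic-in-age OLS fit of one ECG output.

    coeffs is (beta0, beta1, beta2) for the design row (1, x, x^2);
    sigma_nu2 is the residual variance SSE / (n - 3) — the total variance of
    the output around its age trend, which decomposes as
    theta^2 sigma_a^2 + lambda^2.
    """

    output_id: str
    gender: int | str
    coeffs: np.ndarray
    sigma_nu2: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape != (3,):
            raise ValueError("coeffs must be a 3-vector (beta0, beta1, beta2)")
        if self.n < 4:
            raise ValueError(f"need n >= 4 subjects (got n={self.n}): "
                             "residual degrees of freedom n - 3 would be <= 0")
        if self.sigma_nu2 < 0:
            raise ValueError("sigma_nu2 must be >= 0")

    def mean_at(self, x: float | np.ndarray) -> np.ndarray:
        """Fitted mean beta0 + beta1 x + beta2 x^2."""
        x = np.asarray(x, dtype=float)
        return self.coeffs[0] + self.coeffs[1] * x + self.coeffs[2] * x**2


@dataclass(frozen=True)
class RepeatedMeasurePair:
    """Two output vectors from the same subject, sessions ~1 month apart.

    The latent heart age is assumed unchanged between sessions, so the
    difference d = y_first - y_second carries only measurement noise,
    E(d d') = 2 Lambda.
    """

    subject_id: str
    y_first: np.ndarray
    y_second: np.ndarray

    def __post_init__(self) -> None:
        y1 = np.atleast_1d(np.asarray(self.y_first, dtype=float))
        y2 = np.atleast_1d(np.asarray(self.y_second, dtype=float))
        if y1.shape != y2.shape or y1.ndim != 1:
            raise ValueError("y_first and y_second must be 1-d vectors of equal length")
        if not (np.all(np.isfinite(y1)) and np.all(np.isfinite(y2))):
            raise ValueError(f"non-finite measurement for subject {self.subject_id!r}")
        object.__setattr__(self, "y_first", y1)
        object.__setattr__(self, "y_second", y2)

    @property
    def difference(self) -> np.ndarray:
        return self.y_first - self.y_second


@dataclass(frozen=True)
class HeartAgePrediction:
    """Posterior summary for one subject: body age x, posterior mean a_hat,
    and posterior SD (never larger than the prior scale — observing the ECG
    can only sharpen the heart-age distribution)."""

    x: float
    a_hat: float
    posterior_sd: float

    @property
    def delta(self) -> float:
        """Heart-age offset a_hat - x."""
        return self.a_hat - self.x


def grundy_age_adjustment(risk_points: float = 4.5, years_per_point: float = 2.0) -> float:
    """Age adjustment (years) implied by coronary-artery-calcium scoring.

    Grundy's table of effective-age adjustments to the Framingham risk model
    moves subjects above the 75th / below the 25th CAC percentile by about
    4.5 risk points up or down; at roughly 2 years of age per risk point
    that is an adjustment of about +/- 9 years at the extremes.
    """
    return risk_points * years_per_point


def grundy_prior_scale(adjustment_years: float | None = None,
                       percentile: float = 0.875) -> float:
    """Prior SD of heart age implied by the CAC age-adjustment extremes.

    Treating ">75th percentile CAC" as roughly the 87.5th percentile of a
    Normal effective-age distribution, an adjustment of +/- 9 years at that
    percentile corresponds to a standard deviation of
    9 / Phi^-1(0.875) ~= 7.8 years — close to the default sigma_a = 7.5.
    """
    from scipy.stats import norm

    if adjustment_years is None:
        adjustment_years = grundy_age_adjustment()
    return float(adjustment_years / norm.ppf(percentile))


def _design_row(x: float) -> np.ndarray:
    return np.array([1.0, x, x * x])


@dataclass(frozen=True)
class GenderModel:
    """All parameters needed to predict heart age for one gender.

    beta       : k x 3 regression matrix (rows follow ``output_ids``)
    theta      : k-vector of drift coefficients (output-units / year)
    lambda_cov : k x k symmetric positive-definite noise covariance Lambda
    prior      : the N(x, sigma_a^2) prior specification
    """

    gender: int
    beta: np.ndarray
    theta: np.ndarray
    lambda_cov: np.ndarray
    prior: PriorSpec = field(default_factory=PriorSpec)
    output_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        lam = np.atleast_2d(np.asarray(self.lambda_cov, dtype=float))
        k = theta.shape[0]
        if beta.shape != (k, 3):
            raise ValueError(f"beta must be {k} x 3 to match theta, got {beta.shape}")
        if lam.shape != (k, k):
            raise ValueError(f"lambda_cov must be {k} x {k}, got {lam.shape}")
        if not np.allclose(lam, lam.T, rtol=0, atol=1e-10 * max(1.0, np.abs(lam).max())):
            raise ValueError("lambda_cov must be symmetric")
        try:
            np.linalg.cholesky(lam)
        except np.linalg.LinAlgError:
            raise ValueError("lambda_cov must be positive-definite") from None
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "lambda_cov", lam)
        object.__setattr__(self, "_lambda_inv", np.linalg.inv(lam))
        if self.output_ids is not None:
            ids = tuple(self.output_ids)
            if len(ids) != k:
                raise ValueError("output_ids length must equal k")
            object.__setattr__(self, "output_ids", ids)

    @property
    def k(self) -> int:
        return self.theta.shape[0]

    @property
    def lambda_inv(self) -> np.ndarray:
        return self._lambda_inv  # type: ignore[attr-defined]

    def mean_outputs(self, x: float) -> np.ndarray:
        """E(y | x, a = x) = beta @ (1, x, x^2)."""
        return self.beta @ _design_row(float(x))

    @property
    def information(self) -> float:
        """theta' Lambda^-1 theta — the ECG information about the offset."""
        return float(self.theta @ self.lambda_inv @ self.theta)

    @property
    def shrinkage_weight(self) -> float:
        """w = theta' Lambda^-1 theta / (1/sigma_a^2 + theta' Lambda^-1 theta):
        the average fraction of a true heart-age offset recovered by a_hat."""
        q = self.information
        return q / (1.0 / self.prior.sigma_a2 + q)


# --------------------------------------------------------------------------
# estimation
# --------------------------------------------------------------------------

def fit_age_regression(
    ages: Sequence[float],
    outputs: Sequence[float],
    output_id: str = "y",
    gender: int | str = 0,
) -> AgeRegressionFit:
    """Quadratic OLS of one ECG output on body age.

    Fits y_i = beta0 + beta1 x_i + beta2 x_i^2 + nu_i and returns the
    coefficients together with the unbiased residual-variance estimate
    sigma_nu2 = SSE / (n - 3).

    Raises on n < 4 or a rank-deficient design (fewer than 3 distinct ages).
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(outputs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and outputs must be 1-d arrays of equal length")
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"need n >= 4 subjects (got n={n}): "
                         "residual degrees of freedom n - 3 would be <= 0")
    if np.unique(x).size < 3:
        raise ValueError("design matrix (1, x, x^2) is rank-deficient: the "
                         "columns x and x^2 are collinear with the intercept "
                         "(need >= 3 distinct ages)")
    X = np.column_stack([np.ones(n), x, x * x])
    res = sm.OLS(y, X).fit()
    sse = float(res.resid @ res.resid)
    return AgeRegressionFit(
        output_id=output_id,
        gender=gender,
        coeffs=np.asarray(res.params),
        sigma_nu2=sse / (n - 3),
        n=n,
    )


def estimate_lambda(
    pairs: Sequence[RepeatedMeasurePair],
    on_nonpd: str = "diagonal",
) -> np.ndarray:
    """Estimate the measurement-noise covariance Lambda from test-retest pairs.

    Lambda_hat = (1 / 2m) sum_i d_i d_i' with d_i the within-subject
    difference; unbiased because the pair shares its latent heart age, so
    E(d d') = 2 Lambda.  Returns a k x k matrix (1 x 1 for scalar outputs).

    For small m with k >= 2 the estimate can be singular; ``on_nonpd``
    controls what happens then: "diagonal" (default) keeps only the diagonal
    and warns — matching the componentwise use of lambda_jj in theta
    estimation — while "raise" raises instead.
    """
    if on_nonpd not in ("diagonal", "raise"):
        raise ValueError("on_nonpd must be 'diagonal' or 'raise'")
    pairs = list(pairs)
    m = len(pairs)
    if m == 0:
        raise ValueError("need at least one repeated-measure pair (m >= 1)")
    k = pairs[0].y_first.shape[0]
    acc = np.zeros((k, k))
    for p in pairs:
        d = p.difference
        if d.shape[0] != k:
            raise ValueError(f"pair {p.subject_id!r} has {d.shape[0]} outputs, expected {k}")
        acc += np.outer(d, d)
    lam = acc / (2.0 * m)
    if k == 1:
        return lam  # scalar case: zero is a legitimate (degenerate) estimate
    # k >= 2: Lambda^-1 appears in the posterior, so strict PD is required
    try:
        np.linalg.cholesky(lam)
        return lam
    except np.linalg.LinAlgError:
        pass
    if on_nonpd == "raise" or not np.all(np.diag(lam) > 0):
        raise ValueError(
            f"Lambda estimate from m={m} pairs is not positive-definite; "
            "collect more pairs or use the diagonal fallback "
            "(estimate_lambda(..., on_nonpd='diagonal'))"
        )
    warnings.warn(
        f"Lambda estimate from m={m} pairs is not positive-definite; "
        "falling back to its diagonal",
        RuntimeWarning,
        stacklevel=2,
    )
    return np.diag(np.diag(lam))


def estimate_theta(
    fit: AgeRegressionFit,
    lambda_jj: float,
    prior: PriorSpec | None = None,
) -> float:
    """Drift coefficient of one output by variance decomposition.

    theta_hat = sgn(beta1) * sqrt((sigma_nu2 - lambda_jj)) / sigma_a, from
    sigma_nu2 = theta^2 sigma_a^2 + lambda^2.  When the measurement noise
    accounts for all the residual variance (sigma_nu2 <= lambda_jj) the
    square root is undefined and theta_hat is clamped to 0 with a logged
    warning: that output carries no age signal beyond noise and the
    prediction falls back to the prior.  sgn(0) is taken as +1.
    """
    prior = prior or PriorSpec()
    if lambda_jj < 0:
        raise ValueError(f"lambda_jj must be >= 0, got {lambda_jj}")
    excess = fit.sigma_nu2 - lambda_jj
    if excess <= 0:
        if excess < 0:
            logger.warning(
                "output %r (gender %s): residual variance %.4g does not exceed "
                "measurement-noise variance %.4g; setting theta = 0 (output "
                "carries no heart-age signal)",
                fit.output_id, fit.gender, fit.sigma_nu2, lambda_jj,
            )
        return 0.0
    sign = 1.0 if fit.coeffs[1] >= 0 else -1.0
    return sign * np.sqrt(excess) / prior.sigma_a


def fit_gender_model(
    ages: Sequence[float],
    outputs: np.ndarray,
    pairs: Sequence[RepeatedMeasurePair],
    gender: int,
    prior: PriorSpec | None = None,
    output_ids: Sequence[str] | None = None,
    lambda_cov: np.ndarray | None = None,
) -> GenderModel:
    """Fit a complete per-gender model from a cohort plus repeated measures.

    Pipeline: quadratic OLS per output (beta, sigma_nu2), Lambda from the
    pairs (or a precomputed shared ``lambda_cov``, e.g. when the
    repeatability sample is too small to estimate it per gender), then theta
    componentwise using the diagonal of Lambda.
    """
    prior = prior or PriorSpec()
    Y = np.atleast_2d(np.asarray(outputs, dtype=float))
    if Y.shape[0] == len(ages) and Y.shape[1] != len(ages):
        Y = Y.T  # accept n x k as well as k x n
    k = Y.shape[0]
    ids = list(output_ids) if output_ids is not None else [f"y{j + 1}" for j in range(k)]
    lam = np.asarray(lambda_cov, dtype=float) if lambda_cov is not None else estimate_lambda(pairs)
    fits = [
        fit_age_regression(ages, Y[j], output_id=ids[j], gender=gender)
        for j in range(k)
    ]
    beta = np.vstack([f.coeffs for f in fits])
    theta = np.array([
        estimate_theta(fits[j], float(lam[j, j]), prior) for j in range(k)
    ])
    return GenderModel(gender=gender, beta=beta, theta=theta,
                       lambda_cov=lam, prior=prior, output_ids=tuple(ids))


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def predict_heart_age_single(
    x: float,
    y: float,
    coeffs: Sequence[float],
    theta: float,
    lambda2: float,
    prior: PriorSpec | None = None,
) -> HeartAgePrediction:
    """Posterior-mean heart age for a single (k = 1) ECG output.

    a_hat = x + (theta (y - beta' x_) / lambda^2) / (1/sigma_a^2 + theta^2/lambda^2)
    with x_ = (1, x, x^2); posterior SD = (1/sigma_a^2 + theta^2/lambda^2)^-1/2.
    """
    prior = prior or PriorSpec()
    if lambda2 <= 0:
        raise ValueError(f"lambda2 must be > 0, got {lambda2}")
    coeffs = np.asarray(coeffs, dtype=float)
    resid = float(y) - float(coeffs @ _design_row(float(x)))
    precision = 1.0 / prior.sigma_a2 + theta * theta / lambda2
    a_hat = x + (theta * resid / lambda2) / precision
    return HeartAgePrediction(x=float(x), a_hat=float(a_hat),
                              posterior_sd=float(precision**-0.5))


def predict_heart_age(x: float, y: Sequence[float], model: GenderModel) -> HeartAgePrediction:
    """Posterior-mean heart age for k ECG outputs.

    a_hat = x + (theta' Lambda^-1 (y - beta x_)) / (1/sigma_a^2 + theta' Lambda^-1 theta);
    reduces exactly to :func:`predict_heart_age_single` when k = 1.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.shape != (model.k,):
        raise ValueError(f"y has shape {y.shape}, model expects ({model.k},)")
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        name = model.output_ids[bad] if model.output_ids else f"y[{bad}]"
        raise ValueError(f"non-finite value for output {name}")
    resid = y - model.mean_outputs(x)
    precision = 1.0 / model.prior.sigma_a2 + model.information
    a_hat = float(x) + float(model.theta @ model.lambda_inv @ resid) / precision
    return HeartAgePrediction(x=float(x), a_hat=a_hat,
                              posterior_sd=float(precision**-0.5))


def predict_cohort(ages: Sequence[float], outputs: np.ndarray, model: GenderModel) -> np.ndarray:
    """Vectorised posterior means for a cohort: ``outputs`` is n x k.

    Returns the n-vector of a_hat values (posterior SD is the same for all
    subjects of one model; see :class:`GenderModel`).
    """
    x = np.asarray(ages, dtype=float)
    Y = np.atleast_2d(np.asarray(outputs, dtype=float))
    if Y.shape != (x.shape[0], model.k):
        raise ValueError(f"outputs must be n x k = {x.shape[0]} x {model.k}, got {Y.shape}")
    X = np.column_stack([np.ones_like(x), x, x * x])
    resid = Y - X @ model.beta.T
    precision = 1.0 / model.prior.sigma_a2 + model.information
    return x + (resid @ (model.lambda_inv @ model.theta)) / precision


def posterior_density(
    a_grid: Sequence[float],
    x: float,
    y: Sequence[float],
    model: GenderModel,
) -> np.ndarray:
    """Posterior density of heart age on a grid, by direct Bayes' rule.

    Evaluates prior(a | x) * likelihood(y | x, a) pointwise and normalises by
    trapezoidal quadrature.  Serves as the independent numerical oracle for
    the closed-form posterior mean: the grid mean must match
    :func:`predict_heart_age` to numerical tolerance.

    The grid must be strictly increasing and span at least x +/- 5 sigma_a;
    a grid that truncates non-negligible posterior mass (> 1e-6 at the
    edges, relative) is rejected.
    """
    a = np.asarray(a_grid, dtype=float)
    if a.ndim != 1 or a.size < 2 or np.any(np.diff(a) <= 0):
        raise ValueError("a_grid must be a strictly increasing 1-d grid")
    sig = model.prior.sigma_a
    if a[0] > x - 5 * sig or a[-1] < x + 5 * sig:
        raise ValueError(f"a_grid must span at least x +/- 5 sigma_a = "
                         f"[{x - 5 * sig:.1f}, {x + 5 * sig:.1f}]")
    y = np.atleast_1d(np.asarray(y, dtype=float))
    resid0 = y - model.mean_outputs(x)  # residual at a = x
    # log posterior kernel: -(a-x)^2/(2 sigma_a^2) - 1/2 (r - theta(a-x))' L^-1 (r - theta(a-x))
    offs = a - float(x)
    r = resid0[None, :] - offs[:, None] * model.theta[None, :]
    quad = np.einsum("ij,jk,ik->i", r, model.lambda_inv, r)
    logk = -0.5 * offs**2 / model.prior.sigma_a2 - 0.5 * quad
    dens = np.exp(logk - logk.max())
    norm = np.trapezoid(dens, a)
    dens = dens / norm
    if max(dens[0], dens[-1]) > 1e-6 * dens.max():
        raise ValueError("a_grid too narrow: posterior mass at grid edges "
                         "exceeds 1e-6 of the peak")
    return dens


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def model_to_dict(model: GenderModel) -> dict:
    return {
        "gender": model.gender,
        "beta": model.beta.tolist(),
        "theta": model.theta.tolist(),
        "lambda_cov": model.lambda_cov.tolist(),
        "sigma_a": model.prior.sigma_a,
        "output_ids": list(model.output_ids) if model.output_ids else None,
    }


def model_from_dict(d: dict) -> GenderModel:
    """Build a validated GenderModel from its JSON form (invariants —
    symmetry, positive-definiteness, dimensions — are re-checked)."""
    return GenderModel(
        gender=int(d["gender"]),
        beta=np.asarray(d["beta"], dtype=float),
        theta=np.asarray(d["theta"], dtype=float),
        lambda_cov=np.asarray(d["lambda_cov"], dtype=float),
        prior=PriorSpec(float(d.get("sigma_a", DEFAULT_SIGMA_A))),
        output_ids=tuple(d["output_ids"]) if d.get("output_ids") else None,
    )


def save_model(models: Sequence[GenderModel], path: str | Path) -> None:
    payload = {"models": [model_to_dict(m) for m in models]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> dict[int, GenderModel]:
    payload = json.loads(Path(path).read_text())
    models = [model_from_dict(d) for d in payload["models"]]
    return {m.gender: m for m in models}
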