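"""Composite ECG outputs y1, y2 from raw advanced-ECG variables.

The two model inputs are linear scores over transformed raw variables:

    y1 = gamma1' upsilon1,   upsilon1 = (1, Taxis, Pd, sin(FrQRSMax deg),
                                         ln HFP, ln RMSsum, ln SpatialJT)
    y2 = gamma2' upsilon2,   upsilon2 = (1, IIQTVI, UnExQTVI, sin(QRSaxis deg),
                                         Pd, MeanQRS-T, ln IDR)

y1 varies with age and disease, y2 with disease.  The published coefficient
vectors gamma1, gamma2 were obtained by logistic regression of disease
status (healthy non-athlete = 0, imaging-confirmed disease = 1) on the two
feature vectors separately; :func:`fit_composite_coefficients` refits such
coefficients on labelled data.  Angles are in degrees (converted by pi/180),
logs are natural, and raw-variable units must match the units the
coefficients were fitted on — no conversion is attempted here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .model import GenderModel, PriorSpec

__all__ = [
    "ECGRecord",
    "CompositeCoefficients",
    "SeparationError",
    "transform_features",
    "composite_scores",
    "fit_composite_coefficients",
    "published_constants",
    "load_published_model",
    "load_published_coefficients",
]

GROUPS = ("HNA", "ATH", "RFS", "DIS")

_LOG_FIELDS = ("hfp", "rmssum", "spatialjt", "idr")


class SeparationError(RuntimeError):
    """Raised when logistic-regression classes are perfectly separable."""


@dataclass(frozen=True)
class ECGRecord:
    """One subject's raw advanced-ECG variables plus demographics.

    Angles (taxis, frqrsmax, qrsaxis, meanqrst) are in degrees; hfp, rmssum,
    spatialjt and idr feed logarithms and must be strictly positive; units of
    the remaining variables are taken as provided.
    """

    subject_id: str
    gender: int
    body_age: float
    taxis: float
    pd: float
    frqrsmax: float
    hfp: float
    rmssum: float
    spatialjt: float
    iiqtvi: float
    unexqtvi: float
    qrsaxis: float
    meanqrst: float
    idr: float
    group: str = "HNA"

    def __post_init__(self) -> None:
        if self.body_age < 20:
            raise ValueError(f"subject {self.subject_id!r}: body_age must be >= 20")
        for name in _LOG_FIELDS:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(
                    f"subject {self.subject_id!r}: field {name!r} must be "
                    f"strictly positive (log argument), got {v}"
                )
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass(frozen=True)
class CompositeCoefficients:
    """The two 7-vectors of logistic coefficients (intercept + 6 features)."""

    gamma1: np.ndarray
    gamma2: np.ndarray

    def __post_init__(self) -> None:
        g1 = np.asarray(self.gamma1, dtype=float)
        g2 = np.asarray(self.gamma2, dtype=float)
        if g1.shape != (7,) or g2.shape != (7,):
            raise ValueError("gamma1 and gamma2 must each have length 7")
        object.__setattr__(self, "gamma1", g1)
        object.__setattr__(self, "gamma2", g2)


def transform_features(record: ECGRecord) -> tuple[np.ndarray, np.ndarray]:
    """Build the feature vectors (upsilon1, upsilon2) for one record."""
    d2r = math.pi / 180.0
    u1 = np.array([
        1.0,
        record.taxis,
        record.pd,
        math.sin(record.frqrsmax * d2r),
        math.log(record.hfp),
        math.log(record.rmssum),
        math.log(record.spatialjt),
    ])
    u2 = np.array([
        1.0,
        record.iiqtvi,
        record.unexqtvi,
        math.sin(record.qrsaxis * d2r),
        record.pd,
        record.meanqrst,
        math.log(record.idr),
    ])
    return u1, u2


def composite_scores(
    upsilon1: np.ndarray,
    upsilon2: np.ndarray,
    coeffs: CompositeCoefficients,
) -> np.ndarray:
    """y = (gamma1' upsilon1, gamma2' upsilon2)."""
    u1 = np.asarray(upsilon1, dtype=float)
    u2 = np.asarray(upsilon2, dtype=float)
    if u1.shape != (7,) or u2.shape != (7,):
        raise ValueError("upsilon vectors must have length 7")
    return np.array([float(coeffs.gamma1 @ u1), float(coeffs.gamma2 @ u2)])


def fit_composite_coefficients(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Maximum-likelihood logistic coefficients for one composite score.

    ``features`` is n x 7 (intercept column included), ``labels`` is the 0/1
    disease indicator.  Fitted by iteratively reweighted least squares,
    converging when the largest coefficient change drops below 1e-8 (at most
    100 iterations).  Perfectly separable classes have no finite MLE and
    raise :class:`SeparationError`.
    """
    X = np.asarray(features, dtype=float)
    z = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[1] != 7:
        raise ValueError("features must be an n x 7 matrix (intercept included)")
    if X.shape[0] != z.shape[0]:
        raise ValueError("features and labels length mismatch")
    if X.shape[0] <= 7:
        raise ValueError("need n > 7 observations")
    classes = np.unique(z)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must contain both classes, coded 0 and 1")
    try:
        with warnings.catch_warnings():
            # separation drives the Newton step through exp overflow and a
            # singular Hessian; both are converted to SeparationError below
            warnings.simplefilter("ignore")
            res = sm.Logit(z, X).fit(method="newton", maxiter=100, tol=1e-8, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            "classes are perfectly separated; the logistic MLE does not "
            "exist — consider a penalized fit"
        ) from exc
    params = np.asarray(res.params, dtype=float)
    if not res.mle_retvals.get("converged", False) or np.abs(params).max() > 1e3:
        raise SeparationError(
            "logistic fit diverged (near-separation); consider a penalized fit"
        )
    return params


# --------------------------------------------------------------------------
# published constants
# --------------------------------------------------------------------------

def published_constants() -> dict:
    """The shipped JSON resource of published model constants, verbatim."""
    text = resources.files("heartage").joinpath("data/published_model.json").read_text()
    return json.loads(text)


def load_published_coefficients() -> CompositeCoefficients:
    c = published_constants()
    return CompositeCoefficients(gamma1=np.array(c["gamma1"]),
                                 gamma2=np.array(c["gamma2"]))


def load_published_model(gender: int | str) -> tuple[GenderModel, CompositeCoefficients]:
    """The published per-gender model (1 = male, 2 = female; "M"/"F" accepted).

    The noise covariance is obtained by inverting the published Lambda^-1
    exactly as printed; theta, beta and sigma_a are the printed constants.
    """
    aliases = {"m": 1, "male": 1, "1": 1, "f": 2, "female": 2, "2": 2}
    key = aliases.get(str(gender).strip().lower())
    if key is None:
        raise ValueError(f"unknown gender label {gender!r}; use 1/M (male) or 2/F (female)")
    c = published_constants()
    lambda_inv = np.asarray(c["lambda_inv"], dtype=float)
    model = GenderModel(
        gender=key,
        beta=np.asarray(c["beta"][str(key)], dtype=float),
        theta=np.asarray(c["theta"][str(key)], dtype=float),
        lambda_cov=np.linalg.inv(lambda_inv),
        prior=PriorSpec(float(c["sigma_a"])),
        output_ids=tuple(c["output_ids"]),
    )
    return model, load_published_coefficients()
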