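"""Core model: quadratic OLS, variance components, posterior heart age."""

import logging
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartage import (
    AgeRegressionFit,
    GenderModel,
    PriorSpec,
    RepeatedMeasurePair,
    estimate_lambda,
    estimate_theta,
    fit_age_regression,
    load_model,
    posterior_density,
    predict_heart_age,
    predict_heart_age_single,
    save_model,
)
from heartage.model import model_from_dict, model_to_dict

from conftest import random_model

AGES10 = np.array([20, 30, 40, 50, 60, 70, 80, 25, 35, 45], dtype=float)


# --------------------------------------------------------------------------
# quadratic age regression
# --------------------------------------------------------------------------

@pytest.mark.parametrize("shift, expected", [(0.0, (1, 2, 0.1)), (5.0, (6, 2, 0.1))])
def test_noiseless_quadratic_recovered_exactly(shift, expected):
    y = 1 + 2 * AGES10 + 0.1 * AGES10**2 + shift
    fit = fit_age_regression(AGES10, y)
    np.testing.assert_allclose(fit.coeffs, expected, atol=1e-9)
    assert fit.sigma_nu2 == pytest.approx(0.0, abs=1e-12)
    assert fit.n == 10


def _normal_equations_exact(ages, outputs):
    """Independent oracle: solve (X'X) b = X'y in exact rational arithmetic."""
    n = len(ages)
    X = [[Fraction(1), Fraction(a), Fraction(a) ** 2] for a in ages]
    y = [Fraction(v) for v in outputs]
    XtX = [[sum(X[i][r] * X[i][c] for i in range(n)) for c in range(3)] for r in range(3)]
    Xty = [sum(X[i][r] * y[i] for i in range(n)) for r in range(3)]
    # Gaussian elimination with exact fractions
    M = [row[:] + [b] for row, b in zip(XtX, Xty)]
    for col in range(3):
        piv = next(r for r in range(col, 3) if M[r][col] != 0)
        M[col], M[piv] = M[piv], M[col]
        for r in range(3):
            if r != col:
                f = M[r][col] / M[col][col]
                M[r] = [m - f * p for m, p in zip(M[r], M[col])]
    coeffs = [M[r][3] / M[r][r] for r in range(3)]
    resid = [y[i] - sum(c * X[i][j] for j, c in enumerate(coeffs)) for i in range(n)]
    sse = sum(e * e for e in resid)
    return [float(c) for c in coeffs], float(sse / (n - 3))


def test_fit_matches_exact_normal_equations_oracle():
    # fixed 8-point fixture, integer-valued noise so the oracle is exact
    ages = [21, 28, 34, 41, 47, 55, 63, 78]
    outputs = [3, -1, 4, 1, -5, 9, 2, 6]
    coeffs, sigma2 = _normal_equations_exact(ages, outputs)
    fit = fit_age_regression(np.array(ages, float), np.array(outputs, float))
    np.testing.assert_allclose(fit.coeffs, coeffs, rtol=0, atol=1e-10)
    assert fit.sigma_nu2 == pytest.approx(sigma2, rel=1e-10)


def test_fit_rejects_degenerate_designs():
    with pytest.raises(ValueError, match="n >= 4"):
        fit_age_regression([20, 30, 40], [1, 2, 3])
    with pytest.raises(ValueError, match="rank-deficient|distinct"):
        fit_age_regression([30, 30, 30, 40, 40], [1, 2, 3, 4, 5])


def test_fit_result_validates_invariants():
    with pytest.raises(ValueError):
        AgeRegressionFit("y", 1, np.zeros(3), sigma_nu2=-1.0, n=10)
    with pytest.raises(ValueError):
        AgeRegressionFit("y", 1, np.zeros(3), sigma_nu2=1.0, n=3)


# --------------------------------------------------------------------------
# Lambda from repeated measures
# --------------------------------------------------------------------------

def _pair(i, d, base=None):
    d = np.atleast_1d(np.asarray(d, float))
    base = np.zeros_like(d) if base is None else np.asarray(base, float)
    return RepeatedMeasurePair(f"s{i}", base + d, base)


@pytest.mark.parametrize("pairs, expected", [
    ([_pair(0, [0.0])], [[0.0]]),                       # identical repeats
    ([_pair(0, [4.0])], [[8.0]]),                       # 16 / (2*1)
    ([_pair(0, [1, 0]), _pair(1, [0, 2])], [[0.25, 0], [0, 1.0]]),
])
def test_lambda_direct_evaluation(pairs, expected):
    np.testing.assert_allclose(estimate_lambda(pairs), expected, atol=1e-12)


def test_lambda_requires_pairs_and_consistent_k():
    with pytest.raises(ValueError, match="m >= 1"):
        estimate_lambda([])
    with pytest.raises(ValueError, match="outputs"):
        estimate_lambda([_pair(0, [1, 2]), _pair(1, [1.0])])


def test_lambda_singular_estimate_falls_back_to_diagonal():
    # all differences collinear -> rank-1 estimate, not PD for k = 2
    pairs = [_pair(0, [1, 1]), _pair(1, [2, 2])]
    with pytest.warns(RuntimeWarning, match="diagonal"):
        lam = estimate_lambda(pairs)
    np.testing.assert_allclose(lam, np.diag([1.25, 1.25]))
    with pytest.raises(ValueError, match="positive-definite"):
        estimate_lambda(pairs, on_nonpd="raise")


def test_lambda_estimator_is_unbiased(published_models):
    # E(d d') = 2 Lambda, so the mean of Lambda_hat over replicates must
    # approach Lambda (full 2000-replicate check lives in the acceptance suite)
    from heartage import simulate_repeats

    model = published_models[1]
    reps = 300
    acc = np.zeros((2, 2))
    for s in range(reps):
        acc += estimate_lambda(simulate_repeats(model, 15, seed=1000 + s))
    mean = acc / reps
    C = model.lambda_cov
    se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / (15 * reps))
    assert np.all(np.abs(mean - C) < 3 * se)


# --------------------------------------------------------------------------
# theta by variance decomposition
# --------------------------------------------------------------------------

def _fit_with(beta1, sigma_nu2):
    return AgeRegressionFit("y", 1, np.array([0.0, beta1, 0.0]), sigma_nu2, n=100)


def test_theta_decomposition_hand_values(caplog):
    prior = PriorSpec(7.5)
    assert estimate_theta(_fit_with(1.0, 100.0), 100.0, prior) == 0.0
    th = estimate_theta(_fit_with(1.0, 169.0), 100.0, prior)
    assert th == pytest.approx(np.sqrt(69.0) / 7.5)
    assert th == pytest.approx(1.10755, abs=5e-6)
    assert estimate_theta(_fit_with(-1.0, 169.0), 100.0, prior) == pytest.approx(-th)
    # noise exceeding the residual variance clamps theta to 0, with a warning
    with caplog.at_level(logging.WARNING, logger="heartage"):
        assert estimate_theta(_fit_with(1.0, 90.0), 100.0, prior) == 0.0
    assert "theta" in caplog.text or "signal" in caplog.text
    with pytest.raises(ValueError):
        estimate_theta(_fit_with(1.0, 169.0), -1.0, prior)


def test_theta_sign_convention_at_zero_slope():
    assert estimate_theta(_fit_with(0.0, 169.0), 100.0, PriorSpec(7.5)) > 0


def test_variance_decomposition_consistency():
    # on data generated from the drift model, sigma_nu^2 -> theta^2 sigma_a^2 + lambda^2
    rng = np.random.default_rng(42)
    n, theta, lam2, sigma_a = 20_000, 0.25, 1.3, 7.5
    x = rng.uniform(20, 80, n)
    delta = sigma_a * rng.standard_normal(n)
    y = 2.0 + 0.1 * x - 0.001 * x**2 + theta * delta + np.sqrt(lam2) * rng.standard_normal(n)
    fit = fit_age_regression(x, y)
    expected = theta**2 * sigma_a**2 + lam2
    assert abs(fit.sigma_nu2 - expected) / expected < 0.05


# --------------------------------------------------------------------------
# posterior heart age
# --------------------------------------------------------------------------

def test_single_output_prediction_hand_values():
    prior = PriorSpec(7.5)
    coeffs = np.array([1.0, 0.5, 0.0])
    x = 50.0
    mean = 1.0 + 0.5 * x
    # zero residual -> posterior mean is the prior mean
    p = predict_heart_age_single(x, mean, coeffs, theta=0.3, lambda2=1.0, prior=prior)
    assert p.a_hat == pytest.approx(x)
    # theta = 0 -> uninformative output, prior returned whole
    p = predict_heart_age_single(x, mean + 4.0, coeffs, theta=0.0, lambda2=1.0, prior=prior)
    assert p.a_hat == pytest.approx(x)
    assert p.posterior_sd == pytest.approx(7.5)
    # residual 1, theta = 1, lambda2 = 1: a_hat = 50 + 1/(1/56.25 + 1)
    p = predict_heart_age_single(x, mean + 1.0, coeffs, theta=1.0, lambda2=1.0, prior=prior)
    assert p.a_hat == pytest.approx(50.98253, abs=1e-5)
    with pytest.raises(ValueError):
        predict_heart_age_single(x, mean, coeffs, theta=1.0, lambda2=0.0, prior=prior)


def test_multivariate_zero_residual_returns_body_age(male_model):
    for x in np.linspace(20, 80, 13):
        p = predict_heart_age(x, male_model.mean_outputs(x), male_model)
        assert p.a_hat == pytest.approx(x, abs=1e-10)


def test_published_male_worked_example(male_model):
    # outputs of a subject whose latent heart age is 60 at body age 50
    x = 50.0
    y = male_model.mean_outputs(x) + male_model.theta * 10.0
    p = predict_heart_age(x, y, male_model)
    assert male_model.information == pytest.approx(0.166563, abs=1e-6)
    assert p.a_hat == pytest.approx(59.036, abs=1e-3)
    assert p.posterior_sd < male_model.prior.sigma_a


def test_k1_model_reduces_to_single_output_formula():
    rng = np.random.default_rng(11)
    for _ in range(100):
        coeffs = rng.uniform(-5, 5, 3)
        theta = rng.uniform(-1, 1)
        lam2 = rng.uniform(0.1, 5)
        x = rng.uniform(20, 80)
        y = float(coeffs @ [1.0, x, x * x]) + rng.uniform(-10, 10)
        m = GenderModel(1, coeffs[None, :], [theta if theta != 0 else 0.1],
                        [[lam2]], PriorSpec(7.5))
        a = predict_heart_age(x, [y], m).a_hat
        b = predict_heart_age_single(x, y, coeffs, m.theta[0], lam2).a_hat
        assert a == pytest.approx(b, abs=1e-12)


def test_prediction_input_validation(male_model):
    with pytest.raises(ValueError, match="shape"):
        predict_heart_age(50.0, [1.0, 2.0, 3.0], male_model)
    with pytest.raises(ValueError, match="y2"):
        predict_heart_age(50.0, [1.0, np.nan], male_model)


@given(scale=st.floats(-3.0, 3.0), x=st.floats(25.0, 75.0))
@settings(max_examples=50, deadline=None)
def test_offset_is_linear_in_residual(scale, x, male_model):
    """a_hat - x is linear in the residual vector: scaling it scales the offset."""
    base = np.array([0.7, -0.4])
    y1 = male_model.mean_outputs(x) + base
    ys = male_model.mean_outputs(x) + scale * base
    d1 = predict_heart_age(x, y1, male_model).delta
    ds = predict_heart_age(x, ys, male_model).delta
    assert ds == pytest.approx(scale * d1, abs=1e-8)


def test_shrinkage_bound_and_sd_monotonicity():
    rng = np.random.default_rng(5)
    for k in (1, 2, 3):
        m = random_model(rng, k)
        for _ in range(20):
            x = rng.uniform(20, 80)
            y = m.mean_outputs(x) + rng.standard_normal(k) * 3
            p = predict_heart_age(x, y, m)
            resid = y - m.mean_outputs(x)
            bound = abs(m.theta @ m.lambda_inv @ resid) * m.prior.sigma_a2
            assert abs(p.delta) <= bound + 1e-9
            assert 0 < p.posterior_sd <= m.prior.sigma_a
        # growing any |theta_j| strictly sharpens the posterior
        m2 = GenderModel(1, m.beta, m.theta * 1.5, m.lambda_cov, m.prior)
        assert predict_heart_age(50, m2.mean_outputs(50), m2).posterior_sd < \
            predict_heart_age(50, m.mean_outputs(50), m).posterior_sd


# --------------------------------------------------------------------------
# grid-posterior oracle
# --------------------------------------------------------------------------

def _grid(x, sigma_a, n=3001):
    return np.linspace(x - 8 * sigma_a, x + 8 * sigma_a, n)


def test_density_with_zero_theta_is_the_prior(male_model):
    m = GenderModel(1, male_model.beta, [0.0, 0.0], male_model.lambda_cov,
                    male_model.prior)
    x = 47.0
    grid = _grid(x, 7.5)
    dens = posterior_density(grid, x, [5.0, -3.0], m)
    prior = np.exp(-0.5 * (grid - x) ** 2 / 7.5**2) / (7.5 * np.sqrt(2 * np.pi))
    np.testing.assert_allclose(dens, prior, atol=1e-10)


def test_density_normalises_and_mean_matches_closed_form(male_model):
    x = 50.0
    y = male_model.mean_outputs(x) + male_model.theta * 10.0
    grid = _grid(x, 7.5, 6001)
    dens = posterior_density(grid, x, y, male_model)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-9)
    mean = np.trapezoid(grid * dens, grid)
    assert mean == pytest.approx(predict_heart_age(x, y, male_model).a_hat, abs=1e-6)
    assert mean == pytest.approx(59.036, abs=1e-3)


def test_density_rejects_bad_grids(male_model):
    y = male_model.mean_outputs(50.0)
    with pytest.raises(ValueError, match="span"):
        posterior_density(np.linspace(40, 60, 100), 50.0, y, male_model)
    with pytest.raises(ValueError, match="increasing"):
        posterior_density(np.linspace(120, 20, 100), 50.0, y, male_model)


# --------------------------------------------------------------------------
# model container and serialization
# --------------------------------------------------------------------------

def test_model_invariants_enforced(male_model):
    with pytest.raises(ValueError, match="symmetric"):
        GenderModel(1, male_model.beta, male_model.theta, [[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(ValueError, match="positive-definite"):
        GenderModel(1, male_model.beta, male_model.theta, [[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError, match="beta"):
        GenderModel(1, male_model.beta[:1], male_model.theta, male_model.lambda_cov)
    np.testing.assert_allclose(male_model.lambda_cov @ male_model.lambda_inv,
                               np.eye(2), atol=1e-10)


def test_model_json_round_trip(tmp_path, published_models):
    path = tmp_path / "model.json"
    save_model(list(published_models.values()), path)
    loaded = load_model(path)
    for g, m in published_models.items():
        np.testing.assert_allclose(loaded[g].beta, m.beta)
        np.testing.assert_allclose(loaded[g].theta, m.theta)
        np.testing.assert_allclose(loaded[g].lambda_cov, m.lambda_cov)
        assert loaded[g].prior.sigma_a == m.prior.sigma_a
        x, y = 53.0, m.mean_outputs(53.0) + [0.4, -0.2]
        assert predict_heart_age(x, y, loaded[g]).a_hat == \
            pytest.approx(predict_heart_age(x, y, m).a_hat, abs=1e-12)


def test_model_dict_round_trip(male_model):
    m2 = model_from_dict(model_to_dict(male_model))
    assert m2.gender == male_model.gender
    np.testing.assert_allclose(m2.lambda_inv, male_model.lambda_inv)
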