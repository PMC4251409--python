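import numpy as np
import pytest

from heartage import GenderModel, PriorSpec, load_published_model


@pytest.fixture(scope="session")
def male_model() -> GenderModel:
    return load_published_model(1)[0]


@pytest.fixture(scope="session")
def female_model() -> GenderModel:
    return load_published_model(2)[0]


@pytest.fixture(scope="session")
def published_models(male_model, female_model) -> dict[int, GenderModel]:
    return {1: male_model, 2: female_model}


def random_model(rng: np.random.Generator, k: int, sigma_a: float = 7.5) -> GenderModel:
    """A random well-conditioned k-output model for property tests."""
    beta = rng.uniform(-10, 10, size=(k, 3))
    beta[:, 1] = rng.uniform(-0.3, 0.3, size=k)
    beta[:, 2] = rng.uniform(-0.003, 0.003, size=k)
    theta = rng.uniform(0.05, 0.4, size=k) * rng.choice([-1, 1], size=k)
    A = rng.standard_normal((k, k))
    lam = A @ A.T + 0.3 * np.eye(k)
    return GenderModel(gender=1, beta=beta, theta=theta, lambda_cov=lam,
                       prior=PriorSpec(sigma_a))


@pytest.fixture
def model_factory():
    return random_model
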