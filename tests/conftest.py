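import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ddaskf import Dataset, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_kernel(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric kernel with unit diagonal and entries in (0, 1]."""
    K = rng.uniform(0.05, 1.0, size=(n, n))
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


@pytest.fixture(scope="session")
def default_synthetic():
    """The default planted-block dataset (seed 1), shared across tests."""
    return generate_dataset()


@pytest.fixture(scope="session")
def default_dataset(default_synthetic) -> Dataset:
    return default_synthetic.to_dataset()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
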