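import numpy as np
import pytest

from signet import ConnectivityMatrix, default_config, generate_cohort


def random_signed_matrix(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    """Random symmetric signed matrix with zero diagonal, entries in (-1, 1)."""
    w = rng.uniform(-1.0, 1.0, (n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, tuple(f"N{i}" for i in range(n)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 1), shared across tests."""
    return generate_cohort(default_config(seed=1))
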