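import numpy as np
import pytest

from fragnet.network import TimeMode


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def random_stable_matrix(n, rng, mode=TimeMode.CONTINUOUS, margin=None):
    """Random dense matrix shifted/scaled to be stable in the given mode."""
    M = rng.standard_normal((n, n))
    if mode is TimeMode.CONTINUOUS:
        m = margin if margin is not None else rng.uniform(0.1, 1.0)
        return M - (np.max(np.linalg.eigvals(M).real) + m) * np.eye(n)
    rho = np.max(np.abs(np.linalg.eigvals(M)))
    return M / (rho * rng.uniform(1.1, 2.0))


@pytest.fixture
def stable_matrix_factory():
    return random_stable_matrix
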