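import numpy as np
import pytest

from varsel.design import default_design, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def small_dataset():
    """One replicate of the default design at N=225."""
    return generate_dataset(default_design(225, 1, seed=11), 1)


@pytest.fixture
def strong_signal():
    """N=500, M=6: three strong predictors, three nulls, known support."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((500, 6))
    beta = np.array([2.0, -1.5, 1.0, 0.0, 0.0, 0.0])
    Y = 1.0 + X @ beta + rng.standard_normal(500)
    return X, Y, beta


def orthogonal_design(n=64, m=5, seed=3):
    """Columns mean 0, mutually orthogonal, unit sample sd (ddof=1)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, m))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    X = Q * np.sqrt(n - 1)          # sample sd exactly 1, X'X = (n-1) I
    return X
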