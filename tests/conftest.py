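import numpy as np
import pytest


@pytest.fixture(scope="session")
def two_cluster():
    """Perfectly separable two-class clusters in 5 informative dims."""
    rng = np.random.default_rng(7)
    n_per, d = 40, 10
    X = rng.normal(0.0, 0.3, size=(2 * n_per, d))
    X[n_per:, :5] += 10.0
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


@pytest.fixture(scope="session")
def small_selection_problem():
    """D=8 with informative columns {1, 4, 6}; modest class shift."""
    rng = np.random.default_rng(0)
    n_per, d = 30, 8
    X = rng.normal(0.0, 1.0, size=(2 * n_per, d))
    for c in (1, 4, 6):
        X[n_per:, c] += 1.5
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y
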