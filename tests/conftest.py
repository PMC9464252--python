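import numpy as np
import pytest

from fikat import assoc, kernels


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_design(rng):
    """n=200 samples, intercept + 1 covariate, 6 rare variants."""
    n, m = 200, 6
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    G = rng.binomial(2, 0.05, size=(n, m)).astype(float)
    w = rng.uniform(0.5, 1.0, size=m)
    y = rng.normal(size=n)
    return y, X, G, w


@pytest.fixture
def null_model(small_design):
    y, X, _, _ = small_design
    return assoc.fit_null_ols(y, X)


@pytest.fixture
def linear_factor(small_design):
    _, _, G, w = small_design
    return kernels.phi_linear(G, w)
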