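import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def finite_diff_grad(f, x, h=1e-6):
    """Central finite-difference gradient of a scalar function of a d-vector."""
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h * max(1.0, abs(x[i]))
        g[i] = (f(x + e) - f(x - e)) / (2 * e[i])
    return g


def assert_close_rel(actual, expected, rtol=1e-5, atol=1e-8):
    np.testing.assert_allclose(actual, expected, rtol=rtol, atol=atol)
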