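"""Shared fixtures: double-precision mode and small reusable objects."""

import numpy as np
import pytest

from phasegan import nn


@pytest.fixture
def float64_params():
    """Build layers at float64 for high-precision gradient checks."""
    old = nn.get_default_dtype()
    nn.set_default_dtype(np.float64)
    yield
    nn.set_default_dtype(old)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def finite_difference_grad(f, xs, eps=1e-6):
    """Central-difference gradient of a scalar function of numpy arrays."""
    grads = []
    for k, x in enumerate(xs):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp = [a.copy() for a in xs]
            xm = [a.copy() for a in xs]
            xp[k][i] += eps
            xm[k][i] -= eps
            g[i] = (f(*xp) - f(*xm)) / (2 * eps)
        grads.append(g)
    return grads
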