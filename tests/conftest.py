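import numpy as np
import pytest

from nuts4pno import (
    PriorSpec,
    gen_educational_items,
    simulate_responses,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def prior():
    return PriorSpec()


@pytest.fixture
def small_dataset(rng):
    """A small educational dataset: 6 items, 80 examinees, plus truth."""
    items = gen_educational_items(6, rng)
    Y, theta = simulate_responses(items, 80, rng)
    return Y, theta, items


def finite_difference(f, x, h=1e-6):
    """Central finite-difference gradient of a scalar function."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty(x.shape[0])
    for d in range(x.shape[0]):
        xp, xm = x.copy(), x.copy()
        xp[d] += h
        xm[d] -= h
        out[d] = (f(xp) - f(xm)) / (2.0 * h)
    return out
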