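import numpy as np
import pytest

from cyclereg.io_formats import RegistrationConfig
from cyclereg.synthetic_data import make_pair, make_structural_pair


def numeric_gradient(tensor, f, eps=1e-6, sample_every=1):
    """Central finite differences of scalar f() w.r.t. tensor.data."""
    g = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    n = 0
    for _ in it:
        i = it.multi_index
        if n % sample_every:
            n += 1
            continue
        n += 1
        old = tensor.data[i]
        tensor.data[i] = old + eps
        fp = f()
        tensor.data[i] = old - eps
        fm = f()
        tensor.data[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def structural_pair():
    """24^3 structural pair, amplitude 2, used across modules."""
    return make_structural_pair(seed=11)


@pytest.fixture(scope="session")
def toy_pair():
    """Small equal-resolution pair with functional series for fast tests."""
    return make_pair(shape=(12, 12, 12), n_structures=2, amplitude=1.0,
                     seed=5, T=12, functional_factor=3)


@pytest.fixture
def tiny_config():
    return RegistrationConfig(seed=0).tiny()
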