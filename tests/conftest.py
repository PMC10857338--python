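import numpy as np
import pytest

from dod.net import ModelConfig, build_dod


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small-resolution config for fast structural tests."""
    return ModelConfig(num_classes=2, input_size=64, seed=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return build_dod(tiny_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def fd_gradient(fn, x, eps=1e-5):
    """Central-difference gradient of scalar fn at float64 array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xm = x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g
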