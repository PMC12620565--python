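import numpy as np
import pytest

from rwwfit.connectome import StructuralConnectome, normalize_sc
from rwwfit.constants import BiophysicalConstants, HemodynamicConstants
from rwwfit.synthetic import generate_sc


@pytest.fixture
def consts():
    return BiophysicalConstants()

@pytest.fixture
def consts_det():
    return BiophysicalConstants(sigma=0.0)


@pytest.fixture
def hemo():
    return HemodynamicConstants()


@pytest.fixture
def sc3():
    """Hand-written 3-node connectome (raw streamline counts)."""
    w = np.array([[0.0, 5.0, 2.0],
                  [5.0, 0.0, 1.0],
                  [2.0, 1.0, 0.0]])
    return StructuralConnectome(w)


@pytest.fixture
def sc_small_norm():
    """Random connected 6-node connectome, normalized."""
    return normalize_sc(generate_sc(6, density=0.6, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
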