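import numpy as np
import pytest

from eegmci.core import Montage
from eegmci.forward import HeadModel, SourceSpace, build_forward
from eegmci.inverse import compute_inverse


@pytest.fixture(scope="session")
def montage():
    return Montage.standard_1020()


@pytest.fixture(scope="session")
def small_forward(montage):
    """Lead field on a ~50-voxel grid (shared across tests; it is pure)."""
    ss = SourceSpace.regular_grid(n_target=50)
    return build_forward(montage, ss, HeadModel())


@pytest.fixture(scope="session")
def small_inverse(small_forward):
    return compute_inverse(small_forward, regularization=1e-4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
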