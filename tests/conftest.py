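import numpy as np
import pytest

from gridcut import ArchSpec, CropParams, grid_cut, make_arch

DEFAULTS = dict(jaw="mandible", grid_size=1.0, inclusion=7.0, ratio=0.33)


@pytest.fixture(scope="session")
def default_params():
    return CropParams(**DEFAULTS)


@pytest.fixture(scope="session")
def arch_seed1():
    return make_arch(ArchSpec(seed=1))


@pytest.fixture(scope="session")
def crop_seed1(arch_seed1, default_params):
    return grid_cut(arch_seed1.mesh, default_params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
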