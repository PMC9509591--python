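import numpy as np
import pytest

import bonemap as bm


@pytest.fixture
def law():
    return bm.MaterialLaw()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_volume():
    """A constant stored-value 300 grid, 1 mm isotropic at the origin."""
    return bm.CTVolume(
        voxels=np.full((8, 16, 16), 300, dtype=np.int16),
        spacing=np.array([1.0, 1.0, 1.0]),
        rescale_slope=1.0,
        rescale_intercept=-1024.0,
    )


@pytest.fixture
def phantom_design():
    return bm.default_phantom_design()


@pytest.fixture
def noiseless_phantom(phantom_design):
    return bm.make_phantom_volume(phantom_design)


@pytest.fixture
def bone_volume():
    return bm.make_bone_volume(rng_seed=7)


@pytest.fixture
def make_random_ct(rng):
    """Factory for random stored-value volumes spanning all three branches."""

    def factory(shape=(16, 16, 16), lo=-900, hi=2500):
        return bm.CTVolume(
            voxels=rng.integers(lo, hi, size=shape).astype(np.int16),
            spacing=np.array([1.0, 0.7, 0.7]),
            rescale_slope=1.0,
            rescale_intercept=-1024.0,
        )

    return factory
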