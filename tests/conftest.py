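import numpy as np
import pytest

from dvctomo import phantom


@pytest.fixture(scope="session")
def textured_volume():
    """Noise-free textured bone cylinder used across DVC tests."""
    spec = phantom.PhantomSpec(shape=(64, 64, 64), seed=3, texture_amplitude=0.2)
    return phantom.make_bone_phantom(spec)


@pytest.fixture(scope="session")
def full_texture_volume():
    """Texture filling the whole grid (no air) for plane-correlation tests."""
    spec = phantom.PhantomSpec(
        shape=(64, 64, 64), seed=8, texture_amplitude=0.2, cylinder_radius=1e6
    )
    return phantom.make_bone_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
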