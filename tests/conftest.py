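import numpy as np
import pytest

from cect.phantom import PhantomSpec, make_fiber_phantom, make_scene
from cect.volume import GrayVolume


@pytest.fixture(scope="session")
def scene_spec() -> PhantomSpec:
    """Default staining-scene spec at the desk-scale grid."""
    return PhantomSpec(seed=101)


@pytest.fixture(scope="session")
def stained_scene(scene_spec):
    """A mid-staining scene (t = 2 d) with its truth manifest."""
    return make_scene(scene_spec, 2.0)


@pytest.fixture(scope="session")
def fiber_spec() -> PhantomSpec:
    return PhantomSpec(
        shape=(64, 96, 96), voxel_size_um=6.0, seed=202, noise_sd=500.0
    )


@pytest.fixture(scope="session")
def fiber_phantom(fiber_spec):
    return make_fiber_phantom(fiber_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def ramp_volume() -> GrayVolume:
    """Deterministic 16-bit volume with a full-range gradient."""
    x = np.linspace(0, 65535, 16 * 16 * 16).reshape(16, 16, 16)
    return GrayVolume(x.astype(np.uint16), 6.0)
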