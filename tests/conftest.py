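import numpy as np
import pytest

from hsifuse.core_data import HSCube
from hsifuse.synthetic_scenes import SceneSpec, make_plastic_scene, make_registration_target


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cube(rng):
    """4x5 spatial, 10-band random reflectance cube over 400-1000 nm."""
    data = rng.uniform(0.1, 0.9, size=(4, 5, 10))
    return HSCube(data, np.linspace(400, 1000, 10), "VNIR")


@pytest.fixture(scope="session")
def registration_scene():
    spec = SceneSpec(seed=7, vnir_dims=(128, 128), nir_dims=(64, 64))
    return make_registration_target(spec)


@pytest.fixture(scope="session")
def plastic_scene():
    return make_plastic_scene(SceneSpec(seed=11))
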