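import numpy as np
import pytest
import trimesh
from hypothesis import HealthCheck, settings

from aortagrowth.geometry import TriSurface
from aortagrowth.synthetic import AortaParams, make_aorta_surface

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def unit_cube() -> TriSurface:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriSurface(box.vertices, box.faces).oriented()


@pytest.fixture(scope="session")
def test_aorta_params() -> AortaParams:
    """Moderate-resolution aorta used across the suite."""
    return AortaParams(n_circ=48, n_axial=96)


@pytest.fixture(scope="session")
def test_aorta(test_aorta_params):
    return make_aorta_surface(test_aorta_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240222)
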