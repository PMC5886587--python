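import numpy as np
import pytest

from hemoforce.core_fields import GridSpec, VelocityField
from hemoforce.synthetic import make_lv_like_scene, make_plug_flow, make_rigid_rotation


@pytest.fixture(scope="session")
def plug_scene():
    """Sinusoidal plug flow: 40 frames, 3 mm grid, ~100 ml spherical mask."""
    return make_plug_flow()


@pytest.fixture(scope="session")
def rotation_scene():
    """Steady solid-body rotation, omega = 10 rad/s."""
    return make_rigid_rotation()


@pytest.fixture(scope="session")
def lv_scene():
    """Half-ellipsoid ventricle, EDV 175 ml, EF 0.60."""
    return make_lv_like_scene()


@pytest.fixture
def small_grid():
    return GridSpec(spacing=(2e-3, 2e-3, 2e-3), frame_duration=0.05,
                    shape=(9, 9, 9), n_frames=4)


def uniform_velocity(grid: GridSpec, vec=(0.0, 0.0, 0.0)) -> VelocityField:
    values = np.zeros((grid.n_frames, *grid.shape, 3))
    values[:] = np.asarray(vec)
    return VelocityField(grid, values)
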