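import numpy as np
import pytest

from anklemorph.morphometry3d import measure_bones_3d
from anklemorph.phantom_cohort import generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default-spec phantom (cohort-mean anatomy), meshes only."""
    return generate_phantom()


@pytest.fixture(scope="session")
def measured_default(default_phantom):
    """(profile, landmarks, arcs) from the mesh-based 3D pipeline."""
    ph = default_phantom
    return measure_bones_3d(ph.tibia, ph.fibula, ph.talus, ph.frame)


@pytest.fixture(scope="session")
def cohort20():
    """20 sampled specimens, meshes only (no volumes)."""
    return generate_cohort(20, seed=7)


@pytest.fixture(scope="session")
def coarse_volume_phantom():
    """Default phantom rasterized at a coarse test spacing."""
    return generate_phantom(with_volume=True, voxel_spacing=1.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
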