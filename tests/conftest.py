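import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import optrodesim as osim

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_grid() -> osim.VoxelGrid:
    """0.5 mm cube at 10 um voxels (50^3)."""
    return osim.make_grid((0.5, 0.5, 0.5), 10.0)


@pytest.fixture(scope="session")
def paper_pair_50ua() -> osim.ElectrodePair:
    """450-um bipolar pair through the centre of a 2 mm cube frame."""
    return osim.ElectrodePair((1000.0, 1000.0, 775.0), (1000.0, 1000.0, 1225.0), 50e-6)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
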