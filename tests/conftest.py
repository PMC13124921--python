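import numpy as np
import pytest

from amyhist import PhantomSpec, ThreeComponentSpec, generate_phantom
from amyhist.volumes import ScalarVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Cheap phantom (small grid) shared by tests that only need plausibility."""
    pspec = PhantomSpec(grid_dims=(48, 48, 40), seed=7)
    tspec = ThreeComponentSpec(muG2=1.6, piG2=0.5)
    return generate_phantom(pspec, tspec)


@pytest.fixture
def ramp_volume():
    """Linear ramp along axis 0: value = 0.1 * i + 0.5."""
    i = np.arange(12, dtype=float)
    data = np.broadcast_to(
        (0.1 * i + 0.5)[:, None, None], (12, 10, 8)
    ).copy()
    return ScalarVolume.from_voxel_size(data, (2.0, 2.0, 2.0), "suvr")


def volume_from_values(values, kind="suvr"):
    """Pack a 1-D value array into a (n,1,1) volume for histogram APIs."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return ScalarVolume.from_voxel_size(arr, (1.0, 1.0, 1.0), kind)
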