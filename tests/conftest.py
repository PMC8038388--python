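import numpy as np
import pytest

from oxypd.phantom import default_phantom
from oxypd.registration import AffineTransform


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless quarter-size phantom; fast enough for per-test reuse."""
    return default_phantom(seed=11, noise_sigma=0.0, grid_shape=(16, 16, 8),
                           voxel_size=(1.6, 1.6, 4.0))


@pytest.fixture(scope="session")
def study_misalignment():
    """The known session-to-session motion used in recovery tests:
    (3.2, -1.6, 4.0) mm translation plus a 5 degree in-plane rotation about
    the volume center."""
    center = ((np.array([32, 32, 12]) - 1) / 2) * np.array([1.6, 1.6, 4.0])
    return AffineTransform.from_params(
        translation_mm=(3.2, -1.6, 4.0), rotation_deg=(0.0, 0.0, 5.0),
        center_mm=tuple(center))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
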