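import numpy as np
import pytest

from natriq.phantom import PROTOCOLS, make_digital_phantom
from natriq.trajectory import build_da3dpr_trajectory, simulate_psf


@pytest.fixture(scope="session")
def small_traj():
    """Adequately-sampled trajectory for a 16-voxel grid (oracle problems)."""
    return build_da3dpr_trajectory(900, 16, 2.5)


@pytest.fixture(scope="session")
def small_psf(small_traj):
    return simulate_psf(small_traj, 16, voxel_size=2.5)


@pytest.fixture(scope="session")
def phantom32():
    return make_digital_phantom(32, "healthy", seed=11)


@pytest.fixture(scope="session")
def sodium_protocol():
    return PROTOCOLS["sodium"]


@pytest.fixture(scope="session")
def sphere16():
    ax = np.arange(16) - 8
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    return (r <= 5).astype(complex), r
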