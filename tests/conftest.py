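import numpy as np
import pytest

from vlsmlm import (
    CameraModel,
    OpticsModel,
    calibrate,
    simulate_bead_zstack,
)


@pytest.fixture(scope="session")
def optics():
    return OpticsModel()


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def quiet_camera():
    """Noise-free readout in photon units, no offset."""
    return CameraModel(read_noise=0.0, baseline=0.0)


@pytest.fixture(scope="session")
def small_zstack():
    """A reduced calibration scan: 41 steps of 25 nm, 5 frames/step, 20 beads."""
    return simulate_bead_zstack(
        n_beads=20, z_min=-500, z_max=500, z_step=25, frames_per_step=5, seed=1
    )


@pytest.fixture(scope="session")
def small_calibration(small_zstack):
    """Full pipeline result on the reduced scan (shared; ~5 s)."""
    return calibrate(small_zstack)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
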