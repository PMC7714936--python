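import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clearquant.synthetic_data import (
    BeadSceneGroundTruth,
    SceneGroundTruth,
    generate_bead_stack,
    generate_grating_scene,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_bead_scene():
    """Noise-free five-bead stack at the default anisotropic PSF."""
    truth = BeadSceneGroundTruth(seed=3, snr=np.inf)
    stack, centres = generate_bead_stack(truth)
    return truth, stack, centres


@pytest.fixture(scope="session")
def noisy_bead_scene():
    """Five-bead stack at SNR 30 (shot + read noise)."""
    truth = BeadSceneGroundTruth(seed=7, snr=30.0)
    stack, centres = generate_bead_stack(truth)
    return truth, stack, centres


@pytest.fixture()
def noiseless_scene():
    """One exact (noise-free) grating scene with tau = 0.6, scale = 0.85."""
    return generate_grating_scene(SceneGroundTruth(tau=0.6, scale=0.85, seed=1))
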