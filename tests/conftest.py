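import numpy as np
import pytest

from kneekin.simulator import TrialSpec, generate_trial


@pytest.fixture(scope="session")
def clean_fe_trial():
    """Noise-free, drift-free pure flexion/extension recording."""
    return generate_trial(TrialSpec(movement="pure_FE", seed=3))


@pytest.fixture(scope="session")
def noisy_drifting_trial():
    """Combined-rotation recording with heading offset, drift and sensor noise."""
    return generate_trial(
        TrialSpec(
            movement="combined",
            seed=7,
            heading_offset_deg=25.0,
            drift_shank_deg_s=-0.11,
            drift_thigh_deg_s=0.07,
            gyro_noise_deg_s=0.5,
            accel_noise_m_s2=0.196,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
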