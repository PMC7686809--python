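import numpy as np
import pytest

from msmod.config import SimulationConfig
from msmod.synthetic import generate_templates, simulate_subject_eeg


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A short, fast recording: 20 s at 250 Hz, 32 channels, 4 states."""
    return SimulationConfig(
        n_channels=32, sampling_rate=250.0, record_duration=20.0, seed=7
    )


@pytest.fixture(scope="session")
def small_subject(small_cfg):
    return simulate_subject_eeg(small_cfg)


@pytest.fixture(scope="session")
def noiseless_subject():
    cfg = SimulationConfig(
        n_channels=32,
        sampling_rate=250.0,
        record_duration=20.0,
        snr=np.inf,
        seed=11,
    )
    return cfg, *simulate_subject_eeg(cfg)


@pytest.fixture(scope="session")
def planted_templates():
    return generate_templates(32, 4, seed=3)
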