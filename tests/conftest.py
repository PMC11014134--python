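import numpy as np
import pytest
from hypothesis import settings

from fessemg.preprocess import SignalWindow
from fessemg.simulate import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

FS = 8000.0


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def quiet_config() -> SimulationConfig:
    """Artifact-free, noise-free variant for clean-signal checks."""
    return SimulationConfig(seed=1, stim_amplitude_ratio=0.0, noise_rms=0.0)


def make_window(x, channel_id=0, fs=FS, motion="sitting", fatigue="no_fatigue"):
    return SignalWindow(samples=np.asarray(x, dtype=float), channel_id=channel_id,
                        sampling_rate_hz=fs, start_time_s=0.0,
                        motion_label=motion, fatigue_label=fatigue)


@pytest.fixture
def tone_window():
    t = np.arange(4000) / FS
    return make_window(np.sin(2 * np.pi * 100.0 * t))
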