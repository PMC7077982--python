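import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def harmaline_trace():
    """120 s default harmaline-mode accelerometer trace (seed 1)."""
    from tremorkit import gen_tremor_signal, harmaline_config

    return gen_tremor_signal(harmaline_config(duration_s=120.0, seed=1))


@pytest.fixture(scope="session")
def tonic_train_10k():
    """Tonic gamma-renewal train long enough for ~10,000 simple-spike ISIs."""
    from tremorkit import SpikeSynthConfig, gen_spike_train

    return gen_spike_train(SpikeSynthConfig(duration_s=140.0, seed=7))


@pytest.fixture()
def rect_roi():
    from tremorkit import RegionOfInterest

    return RegionOfInterest.rectangle(0, 0, 256, 256, pixel_size_um=0.5)


def sine_trace(freq_hz, fs_hz, duration_s, amp=1.0, phase=0.0):
    from tremorkit import SignalTrace

    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    return SignalTrace(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs_hz)
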