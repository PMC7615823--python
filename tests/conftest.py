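import numpy as np
import pytest

from lfpkit import BackgroundParams, ChannelTrace, EventSchedule, LfpRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_channel_recording(rng):
    """10 s, 2-channel recording of seeded Gaussian noise at 500 Hz."""
    return LfpRecording(
        sampling_rate=500.0,
        channels=(
            ChannelTrace("hippocampus_ipsi", rng.normal(0.0, 30.0, 5000)),
            ChannelTrace("cortex", rng.normal(0.0, 30.0, 5000)),
        ),
        start_time=0.0,
        animal_id="m01",
    )


@pytest.fixture
def default_schedule():
    return EventSchedule()


@pytest.fixture
def quiet_background():
    return BackgroundParams(noise_sd=20.0)


def make_sine(freq, amp, duration, rate, role="hippocampus_ipsi"):
    t = np.arange(int(duration * rate)) / rate
    return ChannelTrace(role, amp * np.sin(2 * np.pi * freq * t))
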