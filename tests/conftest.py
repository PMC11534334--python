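import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tmreeg as tm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 500.0


@pytest.fixture(scope="session")
def montage_neighborhood():
    from tmreeg.cluster_stats import Neighborhood

    return Neighborhood.from_montage(tm.CHANNELS_19)


@pytest.fixture()
def zero_recording():
    """20 s of silence on one channel at 500 Hz."""
    return tm.generate_background(20.0, FS, 1, amplitude_scale=0.0, seed=0)


@pytest.fixture()
def noise_recording():
    """60 s of 1/f background on one channel, 20 µV SD."""
    return tm.generate_background(60.0, FS, 1, amplitude_scale=20.0, seed=7)


@pytest.fixture(scope="session")
def nineteen_channel_recording():
    """Short 19-channel background for montage-wide operations."""
    return tm.generate_background(30.0, FS, 19, amplitude_scale=15.0, seed=3)
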