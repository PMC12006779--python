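import numpy as np
import pytest

from equisense.synth import DeviceSpec, SimulationConfig
from equisense.types import ParticipantRecord

#: Minimal two-device catalog with controlled latency/rate, used where a
#: test needs an exact device property rather than the default fleet.
TEST_DEVICES = (
    DeviceSpec("TestPhone iOS", "iOS", "smartphone", 1.0, 100.0, 0.0),
    DeviceSpec("TestPhone Android", "Android", "smartphone", 1.0, 50.0,
               100.0),
)


@pytest.fixture
def config():
    """Deterministic config on the controlled catalog, no individual
    variation: sessions follow the config-level signal parameters."""
    return SimulationConfig(n_participants=10, devices=TEST_DEVICES,
                            individual_variation=False, seed=42)


@pytest.fixture
def participant():
    return ParticipantRecord("P00000", 45, "female", "MS", "iOS", "iOS 12",
                             "TestPhone iOS", "smartphone")


@pytest.fixture
def android_participant():
    return ParticipantRecord("P00001", 52, "male", "non-MS", "Android",
                             "Android 9", "TestPhone Android", "smartphone")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
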