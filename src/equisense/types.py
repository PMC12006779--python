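"""Core domain types for BYOD sensor-test equivalence analysis.

The unit of observation is one *session*: a participant performing one
active test on their own phone, recorded as raw inertial and touchscreen
streams. Downstream stages attach a quality-control verdict and a scalar
performance feature to each session, and the statistics stage compares
device-defined participant subgroups on those features.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Supported active tests.
TESTS = ("IPS", "IPS_DD", "PT", "SBT", "UTT", "MWT2")

#: Tests performed together in one fixed-sequence run; the 2-minute walk
#: is self-administered separately.
BUNDLED_TESTS = ("IPS", "IPS_DD", "PT", "SBT", "UTT")

#: Nominal test durations in seconds. The U-turn test occupies at most a
#: 60 s window; 55 s is the default programmed duration.
NOMINAL_DURATION = {
    "IPS": 90.0,
    "IPS_DD": 30.0,
    "PT": 30.0,
    "SBT": 30.0,
    "UTT": 55.0,
    "MWT2": 120.0,
}

#: Sensor streams each test must carry.
REQUIRED_STREAMS = {
    "IPS": (),
    "IPS_DD": (),
    "PT": (),
    "SBT": ("accelerometer",),
    "UTT": ("accelerometer", "gyroscope"),
    "MWT2": ("accelerometer",),
}

#: Scalar performance feature per test.
FEATURE_NAME = {
    "IPS": "correct_responses",
    "IPS_DD": "correct_responses",
    "PT": "pinch_count",
    "SBT": "sway_path",
    "UTT": "turn_speed",
    "MWT2": "step_count",
}

STANDARD_GRAVITY = 9.81  # m/s^2


class SchemaError(ValueError):
    """A record or configuration violates its declared invariants."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One enrollee: demographics, disease status and device identity."""

    participant_id: str
    age: int
    sex: str  # {"female", "male"}
    ms_status: str  # {"MS", "non-MS"}
    os_platform: str  # {"iOS", "Android"}
    os_version: str
    device_model: str
    device_class: str  # {"smartphone", "tablet"}

    def __post_init__(self) -> None:
        if self.age < 18:
            raise SchemaError(f"age must be >= 18, got {self.age}")
        if self.sex not in ("female", "male"):
            raise SchemaError(f"unknown sex {self.sex!r}")
        if self.ms_status not in ("MS", "non-MS"):
            raise SchemaError(f"unknown ms_status {self.ms_status!r}")
        if self.os_platform not in ("iOS", "Android"):
            raise SchemaError(f"unknown os_platform {self.os_platform!r}")
        if self.device_class not in ("smartphone", "tablet"):
            raise SchemaError(f"unknown device_class {self.device_class!r}")
        if not self.os_version.startswith(self.os_platform):
            raise SchemaError(
                f"os_version {self.os_version!r} inconsistent with "
                f"platform {self.os_platform!r}"
            )


@dataclass
class SensorStream:
    """One inertial stream: accelerometer (m/s^2) or gyroscope (rad/s)."""

    sensor: str  # {"accelerometer", "gyroscope"}
    t: np.ndarray  # seconds, strictly increasing
    xyz: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.sensor not in ("accelerometer", "gyroscope"):
            raise SchemaError(f"unknown sensor {self.sensor!r}")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise SchemaError("xyz must have shape (n, 3)")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise SchemaError("t and xyz lengths differ")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise SchemaError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size >= 2 else 0.0

    @property
    def mean_rate(self) -> float:
        """Global mean sampling rate in Hz (samples-1 over span)."""
        if self.t.size < 2 or self.duration == 0:
            return 0.0
        return (self.t.size - 1) / self.duration


@dataclass
class TouchEventLog:
    """Raw touchscreen events with normalized coordinates in [0, 1]."""

    t: np.ndarray
    pointer_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    kind: np.ndarray  # {"down", "move", "up"}

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pointer_id = np.asarray(self.pointer_id, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        n = self.t.size
        for arr in (self.pointer_id, self.x, self.y, self.kind):
            if arr.size != n:
                raise SchemaError("touch log columns have unequal lengths")

    def __len__(self) -> int:
        return int(self.t.size)

    @classmethod
    def empty(cls) -> "TouchEventLog":
        return cls(np.array([]), np.array([], dtype=int), np.array([]),
                   np.array([]), np.array([], dtype=object))

    def validate_gestures(self) -> None:
        """Each pointer's events must run down -> moves -> up in order."""
        for pid in np.unique(self.pointer_id):
            kinds = self.kind[self.pointer_id == pid]
            state = "idle"
            for k in kinds:
                if state == "idle":
                    if k != "down":
                        raise SchemaError(
                            f"pointer {pid}: {k} before down")
                    state = "held"
                else:
                    if k == "down":
                        raise SchemaError(f"pointer {pid}: double down")
                    if k == "up":
                        state = "idle"


@dataclass
class ResponseLog:
    """Symbol-matching responses for the processing-speed tests.

    ``shown`` holds symbol tokens, ``selected`` the digit token the user
    picked from a key of ``n_options`` alternatives. A response is correct
    when the selected digit is the key's mapping of the shown symbol; the
    generator encodes the mapping as matching integer suffixes.
    """

    t: np.ndarray
    shown: np.ndarray
    selected: np.ndarray
    n_options: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.shown = np.asarray(self.shown, dtype=object)
        self.selected = np.asarray(self.selected, dtype=object)
        if self.n_options < 2:
            raise SchemaError("n_options must be >= 2")
        if not (self.t.size == self.shown.size == self.selected.size):
            raise SchemaError("response log columns have unequal lengths")

    def __len__(self) -> int:
        return int(self.t.size)

    @classmethod
    def empty(cls, n_options: int = 9) -> "ResponseLog":
        return cls(np.array([]), np.array([], dtype=object),
                   np.array([], dtype=object), n_options)


@dataclass
class SensorSession:
    """One test attempt: raw streams + logs + optional ground truth.

    ``truth`` carries generator-side labels (programmed step count, turn
    schedule, injected anomaly kind, ...) used only by tests; real data
    would leave it empty.
    """

    participant_id: str
    test_type: str
    session_id: str
    start_time: float
    nominal_duration: float
    run_index: int = 0
    streams: dict = field(default_factory=dict)  # sensor -> SensorStream
    touch: Optional[TouchEventLog] = None
    responses: Optional[ResponseLog] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.test_type not in TESTS:
            raise SchemaError(f"unknown test_type {self.test_type!r}")

    def require_streams(self) -> None:
        for sensor in REQUIRED_STREAMS[self.test_type]:
            if sensor not in self.streams:
                raise SchemaError(
                    f"{self.test_type} session missing {sensor} stream")

    @property
    def duration(self) -> float:
        durs = [s.duration for s in self.streams.values()]
        if self.touch is not None and len(self.touch):
            durs.append(float(self.touch.t[-1] - self.touch.t[0]))
        if self.responses is not None and len(self.responses):
            durs.append(float(self.responses.t[-1]))
        return max(durs) if durs else 0.0


@dataclass
class Turn:
    """One detected turn: boundaries, integrated angle, mean yaw rate."""

    start: float
    end: float
    angle_deg: float
    mean_rate: float  # rad/s

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SchemaError("turn end must follow start")


@dataclass(frozen=True)
class FeatureValue:
    """One scalar test-performance feature with provenance."""

    participant_id: str
    session_id: str
    test_type: str
    feature_name: str
    value: float

    def __post_init__(self) -> None:
        if self.feature_name in ("correct_responses", "pinch_count",
                                 "step_count"):
            if self.value < 0 or self.value != int(self.value):
                raise SchemaError(
                    f"{self.feature_name} must be a nonnegative integer")
        elif self.value < 0:
            raise SchemaError(f"{self.feature_name} must be nonnegative")


def asdict(obj) -> dict:
    return dataclasses.asdict(obj)
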