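"""Synthetic cohorts and raw smartphone sensor sessions with ground truth.

Emulates a two-platform bring-your-own-device study: an iOS-heavy cohort
spread over many device models, per-device touch latency and sampling
rate, covariate (age/sex/disease) effects on test performance, and the
anomaly modes the quality-control stage is designed to catch. Every
generated quantity that a downstream stage must recover (step count,
turn schedule, pinch schedule, response script, sway amplitude, injected
anomaly kind) is recorded in ``SensorSession.truth`` so the pipeline can
be tested end to end without any external data.

Signal models are deliberately minimal but closed-form:

* gait: vertical acceleration = gravity + a sinusoid at the cadence
  frequency plus a weaker second harmonic and noise, so peak counting
  recovers the programmed step count;
* turns: yaw-rate boxcar pulses, so angle = rate x width exactly;
* quiet stance: a planar circular sway acceleration (path length
  2*pi*A*f*T in closed form) over a gravity-dominated vertical axis;
* phone-on-table: gravity plus a microtremor floor (SD 0.02 m/s^2),
  two orders of magnitude below handheld stance.
"""
from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .types import (
    BUNDLED_TESTS,
    FEATURE_NAME,
    NOMINAL_DURATION,
    STANDARD_GRAVITY,
    TESTS,
    ParticipantRecord,
    ResponseLog,
    SchemaError,
    SensorSession,
    SensorStream,
    TouchEventLog,
)

SCHEMA_VERSION = 1

ANOMALY_KINDS = ("low_rate", "unstable_rate", "play_to_quit",
                 "phone_on_table", "short_test")

#: Which anomaly kinds make sense for which test.
APPLICABLE_ANOMALIES = {
    "IPS": {"play_to_quit"},
    "IPS_DD": {"play_to_quit"},
    "PT": {"play_to_quit"},
    "SBT": {"low_rate", "unstable_rate", "phone_on_table"},
    "UTT": {"low_rate", "unstable_rate", "phone_on_table", "short_test"},
    "MWT2": {"low_rate", "unstable_rate", "phone_on_table", "short_test"},
}


@dataclass(frozen=True)
class DeviceSpec:
    """One device model: platform, class, sampling rate, touch latency."""

    model: str
    platform: str
    device_class: str
    weight: float
    rate_hz: float
    latency_ms: float


#: Default device catalog. Weights are within-platform and normalized at
#: draw time. Android devices carry higher touch latencies and several
#: sample at 50 Hz, mirroring the heterogeneity of a real BYOD fleet.
DEFAULT_DEVICES = (
    DeviceSpec("iPhone 7", "iOS", "smartphone", 0.10, 100.0, 40.0),
    DeviceSpec("iPhone 8", "iOS", "smartphone", 0.16, 100.0, 35.0),
    DeviceSpec("iPhone SE", "iOS", "smartphone", 0.10, 100.0, 40.0),
    DeviceSpec("iPhone X", "iOS", "smartphone", 0.20, 100.0, 30.0),
    DeviceSpec("iPhone 11", "iOS", "smartphone", 0.22, 100.0, 25.0),
    DeviceSpec("iPhone 12", "iOS", "smartphone", 0.14, 100.0, 20.0),
    DeviceSpec("iPad 7", "iOS", "tablet", 0.08, 100.0, 30.0),
    DeviceSpec("Galaxy S8", "Android", "smartphone", 0.18, 50.0, 120.0),
    DeviceSpec("Galaxy S9", "Android", "smartphone", 0.20, 100.0, 110.0),
    DeviceSpec("Pixel 3", "Android", "smartphone", 0.16, 100.0, 90.0),
    DeviceSpec("P20", "Android", "smartphone", 0.16, 50.0, 130.0),
    DeviceSpec("Moto G7", "Android", "smartphone", 0.12, 50.0, 140.0),
    DeviceSpec("Nokia 7", "Android", "smartphone", 0.13, 50.0, 120.0),
    DeviceSpec("Galaxy Tab A", "Android", "tablet", 0.05, 50.0, 130.0),
)

DEFAULT_OS_VERSIONS = {
    "iOS": {"iOS 11": 0.11, "iOS 12": 0.41, "iOS 13": 0.27,
            "iOS 14": 0.16, "iOS 15": 0.05},
    "Android": {"Android 8": 0.30, "Android 9": 0.45, "Android 10": 0.25},
}

#: Per-test feature model: baseline mean, residual SD, and covariate
#: effects (per-year age slope, male offset, MS offset). Baselines and
#: spreads follow the published cohort-level feature distributions for
#: these six tests; covariate offsets reproduce the reported MS vs
#: non-MS gaps.
DEFAULT_FEATURE_MODEL = {
    "IPS": {"mean": 43.8, "sd": 11.0, "age": -0.25, "male": 1.0, "ms": -1.8},
    "IPS_DD": {"mean": 17.9, "sd": 3.4, "age": -0.06, "male": 0.3,
               "ms": -0.6},
    "PT": {"mean": 30.8, "sd": 12.5, "age": -0.20, "male": 1.0, "ms": -6.5},
    "SBT": {"mean": 21.8, "sd": 20.0, "age": 0.15, "male": 0.0, "ms": 2.2},
    "UTT": {"mean": 1.40, "sd": 0.33, "age": -0.004, "male": 0.05,
            "ms": -0.06},
    "MWT2": {"mean": 190.2, "sd": 36.0, "age": -0.5, "male": 5.0,
             "ms": -3.4},
}

# Cohort centering constants so realized pooled feature means sit at the
# configured baselines regardless of the covariate mix.
_AGE_CENTER = 43.0
_MALE_RATE = 0.37
_MS_RATE = 0.58


@dataclass
class SimulationConfig:
    """All knobs of the generator; one seed fixes every draw.

    ``platform_mix`` is the iOS share of the cohort (the study cohort was
    roughly 82% iOS). ``persistent_low_rate_prob`` is the chance a
    participant's device undersamples on *every* session, the mode that
    excludes whole participants at the sampling-frequency step.
    """

    n_participants: int = 300
    platform_mix: float = 0.817
    ms_rate: float = _MS_RATE
    female_rate: float = 1.0 - _MALE_RATE
    age_mean: float = 43.0
    age_sd: float = 12.5
    devices: Sequence[DeviceSpec] = DEFAULT_DEVICES
    os_versions: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_OS_VERSIONS.items()})
    feature_model: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_FEATURE_MODEL.items()})
    # signal-level parameters
    cadence_hz: float = 1.8          # steps per second
    gait_amplitude: float = 2.0      # m/s^2
    gait_noise_sd: float = 0.2       # m/s^2
    sway_amplitude: float = 0.12     # m/s^2, circular sway radius
    sway_freq_hz: float = 1.0
    stance_noise_sd: float = 0.3     # m/s^2, smooth vertical noise
    table_tremor_sd: float = 0.02    # m/s^2 microtremor floor
    turn_rate: float = 1.5           # rad/s
    n_turns: int = 5
    turn_angle_deg: float = 180.0
    gyro_noise_sd: float = 0.02      # rad/s
    pinch_rate: float = 1.0          # pinches per second
    pinch_duration: float = 0.5      # s
    ips_response_rate: float = 0.7   # responses per second
    ips_dd_response_rate: float = 0.8
    response_accuracy: float = 0.9
    n_options: int = 9
    # anomaly rates (per session)
    anomaly_rates: dict = field(default_factory=lambda: {
        "low_rate": 0.01, "unstable_rate": 0.02, "play_to_quit": 0.05,
        "phone_on_table": 0.04, "short_test": 0.05})
    persistent_low_rate_prob: float = 0.017
    #: draw each participant's programmed test performance from the
    #: feature model (covariate effects + stable individual residual);
    #: when False every session uses the config-level signal parameters.
    individual_variation: bool = True
    # session scheduling
    max_runs: int = 3
    run_count_weights: Sequence[float] = (0.6, 0.3, 0.1)
    mwt2_count_weights: Sequence[float] = (0.15, 0.6, 0.25)  # 0, 1, 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 0:
            raise SchemaError("n_participants must be nonnegative")
        for name in ("platform_mix", "ms_rate", "female_rate",
                     "persistent_low_rate_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{name} must lie in [0, 1], got {v}")
        for kind, rate in self.anomaly_rates.items():
            if kind not in ANOMALY_KINDS:
                raise SchemaError(f"unknown anomaly kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise SchemaError(f"anomaly rate {kind} outside [0, 1]")
        if not self.devices:
            raise SchemaError("device catalog is empty")

    def device(self, model: str) -> DeviceSpec:
        for d in self.devices:
            if d.model == model:
                return d
        raise SchemaError(f"device model {model!r} not in catalog")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "devices" in data:
            data["devices"] = tuple(
                DeviceSpec(**d) if isinstance(d, dict) else d
                for d in data["devices"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _rng_for(config: SimulationConfig, *key_parts) -> np.random.Generator:
    """Deterministic per-object generator derived from the run seed."""
    entropy = [int(config.seed) & 0x7FFFFFFF]
    for part in key_parts:
        if isinstance(part, str):
            entropy.append(zlib.crc32(part.encode()))
        else:
            entropy.append(int(part) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> list[ParticipantRecord]:
    """Draw a cohort whose platform/model/covariate mix follows ``config``."""
    config.validate()
    rng = _rng_for(config, "cohort")
    ios = [d for d in config.devices if d.platform == "iOS"]
    android = [d for d in config.devices if d.platform == "Android"]
    if config.platform_mix > 0 and not ios:
        raise SchemaError("platform_mix > 0 but no iOS devices in catalog")
    if config.platform_mix < 1 and not android:
        raise SchemaError("platform_mix < 1 but no Android devices")

    records = []
    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        on_ios = rng.random() < config.platform_mix
        pool = ios if on_ios else android
        w = np.array([d.weight for d in pool], dtype=float)
        device = pool[rng.choice(len(pool), p=w / w.sum())]
        versions = config.os_versions[device.platform]
        labels = list(versions)
        vw = np.array([versions[v] for v in labels], dtype=float)
        os_version = labels[rng.choice(len(labels), p=vw / vw.sum())]
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                          18, 90))
        records.append(ParticipantRecord(
            participant_id=pid,
            age=age,
            sex="female" if rng.random() < config.female_rate else "male",
            ms_status="MS" if rng.random() < config.ms_rate else "non-MS",
            os_platform=device.platform,
            os_version=os_version,
            device_model=device.model,
            device_class=device.device_class,
        ))
    return records


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def _smooth_noise(n: int, fs: float, sd: float, rng: np.random.Generator,
                  cutoff: float = 0.8) -> np.ndarray:
    """Band-limited Gaussian noise rescaled to a target SD.

    Real resting accelerometer noise is smooth at gait timescales; white
    noise would add unbounded length to the acceleration trajectory, so
    stance noise is low-passed before scaling.
    """
    if n == 0 or sd == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    if n > 30 and cutoff < fs / 2:
        b, a = butter(2, cutoff, fs=fs, btype="low")
        w = filtfilt(b, a, w)
    s = w.std()
    return w * (sd / s) if s > 0 else w


def _gait_accel(t: np.ndarray, fs: float, cadence: float, amp: float,
                noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Vertical-axis gait model: gravity + cadence sinusoid + harmonic."""
    z = (STANDARD_GRAVITY
         + amp * np.sin(2 * np.pi * cadence * t)
         + 0.3 * amp * np.sin(2 * np.pi * 2 * cadence * t + 0.7))
    z = z + _smooth_noise(t.size, fs, noise_sd, rng, cutoff=5.0)
    xy_sd = 0.3 * noise_sd
    x = _smooth_noise(t.size, fs, xy_sd, rng, cutoff=5.0)
    y = _smooth_noise(t.size, fs, xy_sd, rng, cutoff=5.0)
    return np.column_stack([x, y, z])


def programmed_step_count(cadence: float, duration: float) -> int:
    """Peaks of sin(2*pi*cadence*t) on [0, duration): one per step."""
    return int(np.floor(cadence * duration - 0.25)) + 1


def _time_grid(duration: float, fs: float) -> np.ndarray:
    return np.arange(0.0, duration, 1.0 / fs)


def participant_performance(participant: ParticipantRecord,
                            config: SimulationConfig) -> dict:
    """Stable per-participant target feature values.

    One draw per test from the feature model (baseline + covariate
    effects + individual residual), deterministic in the run seed and
    participant id: a person's ability does not change between their
    sessions. Targets are clipped to physically realizable ranges.
    """
    rng = _rng_for(config, "performance", participant.participant_id)
    bounds = {"IPS": (5.0, 85.0), "IPS_DD": (5.0, 28.0), "PT": (5.0, 55.0),
              "SBT": (2.0, 120.0), "UTT": (0.5, 2.5), "MWT2": (60.0, 275.0)}
    out = {}
    for test in TESTS:
        m = config.feature_model[test]
        value = (m["mean"]
                 + m["age"] * (participant.age - _AGE_CENTER)
                 + m["male"] * ((participant.sex == "male") - _MALE_RATE)
                 + m["ms"] * ((participant.ms_status == "MS") - _MS_RATE)
                 + rng.normal(0.0, m["sd"]))
        out[test] = float(np.clip(value, *bounds[test]))
    return out


# ---------------------------------------------------------------------------
# per-test session builders
# ---------------------------------------------------------------------------

def _build_responses(duration: float, rate: float, accuracy: float,
                     n_options: int,
                     rng: np.random.Generator) -> tuple[ResponseLog, int]:
    n = int(np.floor(duration * rate))
    period = 1.0 / rate
    t = period * (np.arange(1, n + 1) + rng.uniform(-0.1, 0.1, size=n))
    t = np.sort(np.clip(t, 0.01, duration - 1e-3))
    shown_idx = rng.integers(0, n_options, size=n)
    correct = rng.random(n) < accuracy
    sel_idx = shown_idx.copy()
    wrong = ~correct
    if wrong.any():
        offsets = rng.integers(1, n_options, size=int(wrong.sum()))
        sel_idx[wrong] = (shown_idx[wrong] + offsets) % n_options
    shown = np.array([f"sym{i}" for i in shown_idx], dtype=object)
    selected = np.array([f"dig{i}" for i in sel_idx], dtype=object)
    return (ResponseLog(t, shown, selected, n_options), int(correct.sum()))


def _build_pinch_log(duration: float, rate: float, pinch_duration: float,
                     latency_s: float,
                     rng: np.random.Generator) -> tuple[TouchEventLog, int]:
    """Two-pointer closing gestures on a fixed schedule.

    The user pinches at a steady period p; each completed pinch costs
    the device's display/registration latency L before the next shape
    appears, so the cumulative latency n*L eats the tail of the fixed
    test window: the device completes floor(n*L/p) fewer pinches than a
    latency-free one, where n is the latency-free count.
    """
    period = 1.0 / rate
    # latency-free count on the schedule k*p, gesture fits if it ends
    # within the window
    n_free = int(np.floor((duration - pinch_duration) / period)) + 1
    n_lost = int(np.floor(n_free * latency_s / period))
    n_target = max(0, n_free - n_lost)
    while (n_target > 0 and (n_target - 1) * (period + latency_s)
           + pinch_duration > duration):
        n_target -= 1
    t, pid, xs, ys, kinds = [], [], [], [], []
    count = 0
    for k in range(n_target):
        start = k * (period + latency_s)
        cx, cy = 0.5 + rng.uniform(-0.2, 0.2, size=2)
        half0 = 0.15
        p_a, p_b = 2 * k, 2 * k + 1
        # two pointers land, close to 10% of the initial separation, lift
        for frac, sep in ((0.0, half0), (0.3, 0.6 * half0),
                          (0.6, 0.25 * half0), (0.9, 0.05 * half0)):
            ts = start + frac * pinch_duration
            kind = "down" if frac == 0.0 else "move"
            t += [ts, ts + 1e-4]
            pid += [p_a, p_b]
            xs += [cx - sep, cx + sep]
            ys += [cy, cy]
            kinds += [kind, kind]
        ts = start + pinch_duration
        t += [ts, ts + 1e-4]
        pid += [p_a, p_b]
        xs += [cx - 0.05 * half0, cx + 0.05 * half0]
        ys += [cy, cy]
        kinds += ["up", "up"]
        count += 1
    order = np.argsort(np.asarray(t))
    log = TouchEventLog(np.asarray(t)[order],
                        np.asarray(pid, dtype=int)[order],
                        np.asarray(xs)[order], np.asarray(ys)[order],
                        np.asarray(kinds, dtype=object)[order])
    return log, count


def _build_sbt_stream(config: SimulationConfig, fs: float,
                      rng: np.random.Generator) -> tuple[SensorStream, dict]:
    duration = NOMINAL_DURATION["SBT"]
    t = _time_grid(duration, fs)
    A, f = config.sway_amplitude, config.sway_freq_hz
    x = A * np.sin(2 * np.pi * f * t)
    y = A * np.cos(2 * np.pi * f * t)
    z = STANDARD_GRAVITY + _smooth_noise(t.size, fs, config.stance_noise_sd,
                                         rng)
    truth = {"sway_amplitude": A, "sway_freq_hz": f,
             "sway_path_noiseless": 2 * np.pi * A * f * duration}
    return SensorStream("accelerometer", t, np.column_stack([x, y, z])), truth


def _build_utt_streams(config: SimulationConfig, fs: float,
                       rng: np.random.Generator) -> tuple[dict, dict]:
    duration = NOMINAL_DURATION["UTT"]
    t = _time_grid(duration, fs)
    omega = config.turn_rate
    angle_rad = np.deg2rad(config.turn_angle_deg)
    width = angle_rad / omega
    n = config.n_turns
    gap = (duration - n * width) / (n + 1)
    if gap <= 0:
        raise SchemaError("turn schedule does not fit the test window")
    yaw = np.zeros_like(t)
    windows = []
    for i in range(n):
        start = gap + i * (width + gap)
        sign = 1.0 if i % 2 == 0 else -1.0
        mask = (t >= start) & (t < start + width)
        yaw[mask] = sign * omega
        windows.append((float(start), float(start + width)))
    yaw = yaw + _smooth_noise(t.size, fs, config.gyro_noise_sd, rng,
                              cutoff=5.0)
    gx = _smooth_noise(t.size, fs, config.gyro_noise_sd, rng, cutoff=5.0)
    gy = _smooth_noise(t.size, fs, config.gyro_noise_sd, rng, cutoff=5.0)
    gyro = SensorStream("gyroscope", t, np.column_stack([gx, gy, yaw]))
    accel = SensorStream(
        "accelerometer", t,
        _gait_accel(t, fs, config.cadence_hz, config.gait_amplitude,
                    config.gait_noise_sd, rng))
    truth = {"turn_count": n, "turn_rate": omega,
             "turn_angle_deg": config.turn_angle_deg,
             "turn_windows": windows}
    return {"accelerometer": accel, "gyroscope": gyro}, truth


def generate_session(participant: ParticipantRecord, test_type: str,
                     config: SimulationConfig, run_index: int = 0,
                     start_time: float = 0.0,
                     rng: Optional[np.random.Generator] = None
                     ) -> SensorSession:
    """Generate one clean (anomaly-free) session for a participant."""
    if test_type not in TESTS:
        raise SchemaError(f"unsupported test_type {test_type!r}")
    device = config.device(participant.device_model)
    if rng is None:
        rng = _rng_for(config, participant.participant_id, test_type,
                       run_index)
    fs = device.rate_hz
    duration = NOMINAL_DURATION[test_type]
    if config.individual_variation:
        perf = participant_performance(participant, config)
        acc = config.response_accuracy
        config = replace(
            config,
            ips_response_rate=perf["IPS"] / (acc * NOMINAL_DURATION["IPS"]),
            ips_dd_response_rate=perf["IPS_DD"]
            / (acc * NOMINAL_DURATION["IPS_DD"]),
            pinch_rate=perf["PT"] / NOMINAL_DURATION["PT"],
            sway_amplitude=perf["SBT"] / (2 * np.pi * config.sway_freq_hz
                                          * NOMINAL_DURATION["SBT"]),
            turn_rate=perf["UTT"],
            cadence_hz=perf["MWT2"] / NOMINAL_DURATION["MWT2"],
        )
    session = SensorSession(
        participant_id=participant.participant_id,
        test_type=test_type,
        session_id=f"{participant.participant_id}-{test_type}-{run_index}",
        start_time=start_time,
        nominal_duration=duration,
        run_index=run_index,
    )
    truth: dict = {"device_rate_hz": fs, "latency_ms": device.latency_ms}

    if test_type in ("IPS", "IPS_DD"):
        rate = (config.ips_response_rate if test_type == "IPS"
                else config.ips_dd_response_rate)
        session.responses, n_correct = _build_responses(
            duration, rate, config.response_accuracy, config.n_options, rng)
        truth["correct_responses"] = n_correct
    elif test_type == "PT":
        session.touch, count = _build_pinch_log(
            duration, config.pinch_rate, config.pinch_duration,
            device.latency_ms / 1000.0, rng)
        truth["pinch_count"] = count
        truth["pinch_rate"] = config.pinch_rate
    elif test_type == "SBT":
        stream, t_extra = _build_sbt_stream(config, fs, rng)
        session.streams["accelerometer"] = stream
        truth.update(t_extra)
    elif test_type == "UTT":
        streams, t_extra = _build_utt_streams(config, fs, rng)
        session.streams.update(streams)
        truth.update(t_extra)
    elif test_type == "MWT2":
        t = _time_grid(duration, fs)
        session.streams["accelerometer"] = SensorStream(
            "accelerometer", t,
            _gait_accel(t, fs, config.cadence_hz, config.gait_amplitude,
                        config.gait_noise_sd, rng))
        truth["step_count"] = programmed_step_count(config.cadence_hz,
                                                    duration)
        truth["cadence_hz"] = config.cadence_hz
    session.truth = truth
    return session


# ---------------------------------------------------------------------------
# anomaly injection
# ---------------------------------------------------------------------------

def _resample_stream(stream: SensorStream, new_rate: float) -> SensorStream:
    t0, t1 = stream.t[0], stream.t[-1]
    new_t = np.arange(t0, t1, 1.0 / new_rate)
    xyz = np.column_stack([
        np.interp(new_t, stream.t, stream.xyz[:, k]) for k in range(3)])
    return SensorStream(stream.sensor, new_t, xyz)


def inject_anomaly(session: SensorSession, kind: str,
                   config: Optional[SimulationConfig] = None,
                   rng: Optional[np.random.Generator] = None
                   ) -> SensorSession:
    """Return a copy of ``session`` rewritten to exhibit one anomaly mode."""
    if kind not in ANOMALY_KINDS:
        raise SchemaError(f"unknown anomaly kind {kind!r}")
    if kind not in APPLICABLE_ANOMALIES[session.test_type]:
        raise SchemaError(
            f"anomaly {kind!r} not applicable to {session.test_type}")
    config = config or SimulationConfig(n_participants=0)
    if rng is None:
        rng = _rng_for(config, session.session_id, kind)

    out = SensorSession(
        participant_id=session.participant_id,
        test_type=session.test_type,
        session_id=session.session_id,
        start_time=session.start_time,
        nominal_duration=session.nominal_duration,
        run_index=session.run_index,
        streams=dict(session.streams),
        touch=session.touch,
        responses=session.responses,
        truth=dict(session.truth),
    )
    out.truth["anomaly"] = kind

    if kind == "low_rate":
        new_rate = 25.0
        out.streams = {name: _resample_stream(s, new_rate)
                       for name, s in out.streams.items()}
        out.truth["injected_rate_hz"] = new_rate
    elif kind == "unstable_rate":
        # a 2 s window where the local rate drops to 20 Hz
        low_rate, width = 20.0, 2.0
        new_streams = {}
        for name, s in out.streams.items():
            t0 = s.t[0] + 0.25 * s.duration
            inside = (s.t >= t0) & (s.t < t0 + width)
            step = max(1, int(round(s.mean_rate / low_rate)))
            keep = ~inside
            idx_inside = np.flatnonzero(inside)[::step]
            keep[idx_inside] = True
            new_streams[name] = SensorStream(s.sensor, s.t[keep],
                                             s.xyz[keep])
        out.streams = new_streams
        out.truth["dip_window"] = width
    elif kind == "play_to_quit":
        if session.test_type in ("IPS", "IPS_DD"):
            n_opts = (session.responses.n_options if session.responses
                      is not None else 9)
            n = 40
            t = 0.12 * np.arange(1, n + 1)
            shown = np.array([f"sym{i}" for i in
                              rng.integers(0, n_opts, size=n)], dtype=object)
            selected = np.array([f"dig{i}" for i in
                                 rng.integers(0, n_opts, size=n)],
                                dtype=object)
            out.responses = ResponseLog(t, shown, selected, n_opts)
            out.truth["correct_responses"] = None
        else:  # PT: no screen interaction at all
            out.touch = TouchEventLog.empty()
            out.truth["pinch_count"] = None
    elif kind == "phone_on_table":
        new_streams = {}
        for name, s in out.streams.items():
            if s.sensor == "accelerometer":
                xyz = np.column_stack([
                    rng.normal(0, config.table_tremor_sd, s.t.size),
                    rng.normal(0, config.table_tremor_sd, s.t.size),
                    STANDARD_GRAVITY
                    + rng.normal(0, config.table_tremor_sd, s.t.size)])
            else:
                xyz = rng.normal(0, 0.005, size=(s.t.size, 3))
            new_streams[name] = SensorStream(s.sensor, s.t, xyz)
        out.streams = new_streams
    elif kind == "short_test":
        cutoff = 35.0 if session.test_type == "UTT" else 95.0
        new_streams = {}
        for name, s in out.streams.items():
            keep = s.t - s.t[0] <= cutoff
            new_streams[name] = SensorStream(s.sensor, s.t[keep],
                                             s.xyz[keep])
        out.streams = new_streams
        out.truth["truncated_to_s"] = cutoff
    return out


def flip_orientation(session: SensorSession, fraction: float = 0.15,
                     ) -> SensorSession:
    """Rotate the phone onto its side for a contiguous chunk of the test.

    Swaps the gravity-bearing axis (z -> x) for ``fraction`` of the
    duration; used to build labeled fixtures for the orientation-
    stability flag.
    """
    out = SensorSession(
        participant_id=session.participant_id,
        test_type=session.test_type,
        session_id=session.session_id,
        start_time=session.start_time,
        nominal_duration=session.nominal_duration,
        run_index=session.run_index,
        streams={},
        touch=session.touch,
        responses=session.responses,
        truth=dict(session.truth),
    )
    for name, s in session.streams.items():
        xyz = s.xyz.copy()
        if s.sensor == "accelerometer":
            t0 = s.t[0] + 0.4 * s.duration
            mask = (s.t >= t0) & (s.t < t0 + fraction * s.duration)
            xyz[mask] = xyz[mask][:, [2, 1, 0]]
        out.streams[name] = SensorStream(s.sensor, s.t, xyz)
    out.truth["orientation_flip_fraction"] = fraction
    return out


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

def generate_sessions(cohort: Iterable[ParticipantRecord],
                      config: SimulationConfig) -> list[SensorSession]:
    """Full session history for a cohort, with anomalies at configured rates.

    Each participant performs 1..max_runs bundled runs (the five
    fixed-sequence tests) plus an independent number of 2-minute walks.
    Sessions of persistently undersampling devices are all rewritten with
    the low-rate anomaly.
    """
    sessions: list[SensorSession] = []
    for participant in cohort:
        rng = _rng_for(config, "schedule", participant.participant_id)
        persistent_low = rng.random() < config.persistent_low_rate_prob
        n_runs = 1 + rng.choice(len(config.run_count_weights),
                                p=np.asarray(config.run_count_weights)
                                / np.sum(config.run_count_weights))
        n_walks = rng.choice(len(config.mwt2_count_weights),
                             p=np.asarray(config.mwt2_count_weights)
                             / np.sum(config.mwt2_count_weights))
        clock = 0.0
        for run in range(int(n_runs)):
            for test in BUNDLED_TESTS:
                s = generate_session(participant, test, config, run_index=run,
                                     start_time=clock)
                s = _maybe_inject(s, config, rng, persistent_low)
                sessions.append(s)
                clock += NOMINAL_DURATION[test] + 30.0
            clock += 3600.0
        for w in range(int(n_walks)):
            s = generate_session(participant, "MWT2", config, run_index=w,
                                 start_time=clock)
            s = _maybe_inject(s, config, rng, persistent_low)
            sessions.append(s)
            clock += NOMINAL_DURATION["MWT2"] + 3600.0
    return sessions


def _maybe_inject(session: SensorSession, config: SimulationConfig,
                  rng: np.random.Generator,
                  persistent_low: bool) -> SensorSession:
    if persistent_low and session.streams:
        return inject_anomaly(session, "low_rate", config, rng)
    applicable = APPLICABLE_ANOMALIES[session.test_type]
    for kind in ANOMALY_KINDS:
        if kind in applicable and rng.random() < config.anomaly_rates.get(
                kind, 0.0):
            return inject_anomaly(session, kind, config, rng)
    return session


# ---------------------------------------------------------------------------
# feature-table generation (statistics-scale shortcut)
# ---------------------------------------------------------------------------

def generate_feature_table(config: SimulationConfig,
                           shifts: Optional[dict] = None,
                           cohort: Optional[list] = None):
    """Cohort plus per-participant feature table drawn from the feature model.

    ``shifts`` maps ``(test_type, subgroup_label)`` to an additive mean
    shift; the label is matched against the participant's platform, OS
    version, device model or device class. Ground-truth shifts are
    stored per row for recovery tests. Bypasses signal synthesis so the
    statistics stage can be exercised at study scale.
    """
    import pandas as pd

    shifts = dict(shifts or {})
    if cohort is None:
        cohort = generate_cohort(config)
    labels = ({d.model for d in config.devices}
              | {d.platform for d in config.devices}
              | {d.device_class for d in config.devices}
              | {v for plat in config.os_versions.values() for v in plat})
    for test, label in shifts:
        if test not in TESTS:
            raise SchemaError(f"unknown test {test!r} in shifts")
        if label not in labels:
            raise SchemaError(f"unknown subgroup label {label!r} in shifts")

    rng = _rng_for(config, "feature_table")
    rows = []
    for p in cohort:
        attrs = {p.os_platform, p.os_version, p.device_model, p.device_class}
        for test in TESTS:
            m = config.feature_model[test]
            shift = sum(v for (t, lab), v in shifts.items()
                        if t == test and lab in attrs)
            value = (m["mean"]
                     + m["age"] * (p.age - _AGE_CENTER)
                     + m["male"] * ((p.sex == "male") - _MALE_RATE)
                     + m["ms"] * ((p.ms_status == "MS") - _MS_RATE)
                     + shift
                     + rng.normal(0.0, m["sd"]))
            rows.append({"participant_id": p.participant_id,
                         "test_type": test,
                         "feature_name": FEATURE_NAME[test],
                         "value": value,
                         "true_shift": shift})
    cohort_df = cohort_to_frame(cohort)
    return cohort_df, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ("participant_id", "age", "sex", "ms_status", "os_platform",
                  "os_version", "device_model", "device_class")


def cohort_to_frame(cohort: Iterable[ParticipantRecord]):
    import pandas as pd
    return pd.DataFrame([{c: getattr(p, c) for c in COHORT_COLUMNS}
                         for p in cohort], columns=list(COHORT_COLUMNS))


def write_cohort_csv(cohort: Iterable[ParticipantRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[ParticipantRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            row["age"] = int(row["age"])
            records.append(ParticipantRecord(**{c: row[c]
                                                for c in COHORT_COLUMNS}))
    return records


def _session_to_dict(s: SensorSession) -> dict:
    def arr(a, nd=6):
        return np.round(np.asarray(a, dtype=float), nd).tolist()

    d = {
        "schema_version": SCHEMA_VERSION,
        "session_id": s.session_id,
        "participant_id": s.participant_id,
        "test_type": s.test_type,
        "start_time": s.start_time,
        "nominal_duration": s.nominal_duration,
        "run_index": s.run_index,
        "streams": [
            {"sensor": st.sensor, "t": arr(st.t),
             "x": arr(st.xyz[:, 0]), "y": arr(st.xyz[:, 1]),
             "z": arr(st.xyz[:, 2])}
            for st in s.streams.values()],
        "truth": _jsonable(s.truth),
    }
    if s.touch is not None:
        d["touch"] = {"t": arr(s.touch.t),
                      "pointer_id": s.touch.pointer_id.tolist(),
                      "x": arr(s.touch.x), "y": arr(s.touch.y),
                      "kind": list(s.touch.kind)}
    if s.responses is not None:
        d["responses"] = {"t": arr(s.responses.t),
                          "shown": list(s.responses.shown),
                          "selected": list(s.responses.selected),
                          "n_options": s.responses.n_options}
    return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _session_from_dict(d: dict) -> SensorSession:
    session = SensorSession(
        participant_id=d["participant_id"],
        test_type=d["test_type"],
        session_id=d["session_id"],
        start_time=d["start_time"],
        nominal_duration=d["nominal_duration"],
        run_index=d.get("run_index", 0),
        truth=d.get("truth", {}),
    )
    for st in d.get("streams", []):
        session.streams[st["sensor"]] = SensorStream(
            st["sensor"], np.asarray(st["t"]),
            np.column_stack([st["x"], st["y"], st["z"]]))
    if "touch" in d:
        tc = d["touch"]
        session.touch = TouchEventLog(
            np.asarray(tc["t"]), np.asarray(tc["pointer_id"], dtype=int),
            np.asarray(tc["x"]), np.asarray(tc["y"]),
            np.asarray(tc["kind"], dtype=object))
    if "responses" in d:
        rp = d["responses"]
        session.responses = ResponseLog(
            np.asarray(rp["t"]), np.asarray(rp["shown"], dtype=object),
            np.asarray(rp["selected"], dtype=object), rp["n_options"])
    return session


def write_sessions_jsonl(sessions: Iterable[SensorSession], path) -> None:
    with open(path, "w") as fh:
        for s in sessions:
            fh.write(json.dumps(_session_to_dict(s)) + "\n")


def read_sessions_jsonl(path) -> list[SensorSession]:
    sessions = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sessions.append(_session_from_dict(json.loads(line)))
    return sessions


def write_sessions_csvdir(sessions: Iterable[SensorSession], outdir) -> None:
    """Directory-of-CSV dialect: one ``t,x,y,z`` file per sensor stream."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        base = outdir / s.session_id
        base.mkdir(exist_ok=True)
        for name, st in s.streams.items():
            with open(base / f"{name}.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["t", "x", "y", "z"])
                for i in range(st.t.size):
                    w.writerow([f"{st.t[i]:.6f}", f"{st.xyz[i, 0]:.6f}",
                                f"{st.xyz[i, 1]:.6f}", f"{st.xyz[i, 2]:.6f}"])
        meta = {k: v for k, v in _session_to_dict(s).items()
                if k != "streams"}
        with open(base / "session.json", "w") as fh:
            json.dump(meta, fh)
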