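"""Quality control: sampling-frequency filtering and validity flags.

Two screening steps run before any feature is trusted. First, a session
is excluded outright if any sensor stream was recorded at a low
(<= 33 Hz overall) or unstable (any 1 s window <= 33 Hz) sampling rate,
33 Hz being the minimum rate at which gait can be assessed reliably.
Second, per-test validity flags catch play-to-quit behavior (random fast
responses, no screen interaction, phone left on a table) and
insufficient data (too few turns, implausible turn angles, truncated
gait tests). A session is valid iff the rate check passes and no flag is
raised. All inequality boundaries are inclusive on the invalid side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.stats import binomtest

from .types import (
    STANDARD_GRAVITY,
    ResponseLog,
    SchemaError,
    SensorSession,
    SensorStream,
    TouchEventLog,
    Turn,
)
from . import features as _features

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """All QC cut-offs; defaults follow the published flag criteria.

    The play-to-quit rule for the symbol tests is this module's
    operationalization of "response selected independently of symbol":
    flag when a one-sided binomial test cannot distinguish the observed
    accuracy from the chance level 1/n_options (p > chance_margin) AND
    the median inter-response interval is below min_response_interval.
    """

    min_rate_hz: float = 33.0
    stability_window_s: float = 1.0
    stability_step_s: float = 0.5
    orientation_stability_fraction: float = 0.90
    utt_min_turns: int = 3          # invalid if count <= 3
    utt_turn_angle_low_deg: float = 90.0   # invalid if angle <= 90
    utt_turn_angle_high_deg: float = 270.0  # invalid if angle >= 270
    utt_min_duration_s: float = 40.0        # invalid if duration <= 40
    mwt2_min_duration_s: float = 105.0      # invalid if duration <= 105
    sbt_step_limit: int = 2
    table_still_sd: float = 0.1     # m/s^2
    gravity_tolerance: float = 0.05  # relative, for phone-on-table
    chance_margin: float = 1e-3
    min_response_interval_s: float = 0.5
    gravity_axis_cutoff_hz: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.orientation_stability_fraction < 1.0:
            raise SchemaError("orientation fraction must lie in (0, 1)")
        for name in ("min_rate_hz", "stability_window_s",
                     "utt_min_duration_s", "mwt2_min_duration_s",
                     "table_still_sd", "min_response_interval_s"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be positive")


@dataclass
class RateDetail:
    global_rate_hz: float
    min_window_rate_hz: float
    reason: str = ""


@dataclass
class QCResult:
    """Verdict for one session: rate check, flags, overall validity."""

    session_id: str
    test_type: str
    rate_ok: bool
    rate_detail: Optional[RateDetail]
    flags: frozenset = field(default_factory=frozenset)

    @property
    def valid(self) -> bool:
        return self.rate_ok and not self.flags


# ---------------------------------------------------------------------------
# sampling frequency
# ---------------------------------------------------------------------------

def check_sampling_frequency(stream: SensorStream,
                             thresholds: QCThresholds = QCThresholds()
                             ) -> tuple[bool, RateDetail]:
    """Global and windowed rate check: fail on any rate <= min_rate_hz.

    The global rate is (n-1)/span; the local rate is the sample count in
    each sliding window (width ``stability_window_s``, step
    ``stability_step_s``) divided by the window width. Streams with
    fewer than 2 samples fail with a distinct reason code.
    """
    t = stream.t
    if t.size < 2:
        return False, RateDetail(0.0, 0.0, "insufficient_samples")
    span = float(t[-1] - t[0])
    global_rate = (t.size - 1) / span
    win, step = thresholds.stability_window_s, thresholds.stability_step_s
    if span <= win:
        min_window = global_rate
    else:
        starts = np.arange(t[0], t[-1] - win + 1e-9, step)
        counts = (np.searchsorted(t, starts + win, side="left")
                  - np.searchsorted(t, starts, side="left"))
        min_window = float(counts.min()) / win
    ok = (global_rate > thresholds.min_rate_hz
          and min_window > thresholds.min_rate_hz)
    return ok, RateDetail(float(global_rate), float(min_window),
                          "" if ok else "rate_at_or_below_threshold")


# ---------------------------------------------------------------------------
# per-test flags
# ---------------------------------------------------------------------------

def flag_symbol_play_to_quit(responses: ResponseLog,
                             thresholds: QCThresholds = QCThresholds()
                             ) -> bool:
    """Chance-level accuracy at fast pacing on the symbol tests."""
    if responses is None or len(responses) == 0:
        return True  # no evidence of accordant execution
    n = len(responses)
    correct = sum(1 for s, d in zip(responses.shown, responses.selected)
                  if s.removeprefix("sym") == d.removeprefix("dig"))
    p_chance = 1.0 / responses.n_options
    above_chance_p = binomtest(correct, n, p_chance,
                               alternative="greater").pvalue
    chance_level = above_chance_p > thresholds.chance_margin
    if n >= 2:
        fast = (float(np.median(np.diff(responses.t)))
                < thresholds.min_response_interval_s)
    else:
        fast = True
    return bool(chance_level and fast)


def flag_no_touch(touch: Optional[TouchEventLog]) -> bool:
    """No screen interaction at all during the pinching test."""
    if touch is None or len(touch) == 0:
        return True
    touch.validate_gestures()  # malformed logs raise SchemaError
    return False


def flag_phone_on_table(accel: SensorStream,
                        thresholds: QCThresholds = QCThresholds()) -> bool:
    """Still, gravity-dominated signal: device resting on a surface."""
    if accel is None:
        raise SchemaError("phone-on-table flag requires an accelerometer")
    mag = np.linalg.norm(accel.xyz, axis=1)
    still = float(mag.std()) < thresholds.table_still_sd
    near_gravity = (abs(float(mag.mean()) - STANDARD_GRAVITY)
                    <= thresholds.gravity_tolerance * STANDARD_GRAVITY)
    if still and not near_gravity:
        log.warning("still stream with non-gravity magnitude "
                    "(mean %.2f m/s^2): anomalous but not table-like",
                    float(mag.mean()))
    return bool(still and near_gravity)


def flag_steps_during_sbt(accel: SensorStream,
                          thresholds: QCThresholds = QCThresholds()) -> bool:
    """Walking during the balance test, via the gait step detector."""
    return _features.count_steps(accel) >= thresholds.sbt_step_limit


def flag_orientation(accel: SensorStream,
                     thresholds: QCThresholds = QCThresholds()) -> bool:
    """Unstable main phone orientation during the U-turn test.

    The dominant gravity axis is the axis of largest |low-pass
    component| per sample; the flag is raised when the fraction of
    samples on the modal axis is <= the stability fraction.
    """
    fs = accel.mean_rate
    cutoff = thresholds.gravity_axis_cutoff_hz
    if accel.t.size < 30 or cutoff >= fs / 2:
        grav = np.tile(accel.xyz.mean(axis=0), (accel.t.size, 1))
    else:
        b, a = butter(1, cutoff, fs=fs, btype="low")
        grav = filtfilt(b, a, accel.xyz, axis=0)
    axis = np.argmax(np.abs(grav), axis=1)
    modal_fraction = float(np.bincount(axis, minlength=3).max()) / axis.size
    return modal_fraction <= thresholds.orientation_stability_fraction


def flag_utt_insufficient(turns: list[Turn], duration: float,
                          thresholds: QCThresholds = QCThresholds()
                          ) -> frozenset:
    """Insufficient-data flags for the U-turn test."""
    flags = set()
    if len(turns) <= thresholds.utt_min_turns:
        flags.add("too_few_turns")
    if any(tr.angle_deg <= thresholds.utt_turn_angle_low_deg
           or tr.angle_deg >= thresholds.utt_turn_angle_high_deg
           for tr in turns):
        flags.add("bad_turn_angle")
    if duration <= thresholds.utt_min_duration_s:
        flags.add("too_short")
    return frozenset(flags)


# ---------------------------------------------------------------------------
# session-level evaluation
# ---------------------------------------------------------------------------

def evaluate_session(session: SensorSession,
                     thresholds: QCThresholds = QCThresholds()) -> QCResult:
    """Rate check, then every flag applicable to the session's test."""
    session.require_streams()
    rate_ok, detail = True, None
    for stream in session.streams.values():
        ok, d = check_sampling_frequency(stream, thresholds)
        if detail is None or not ok:
            detail = d
        if not ok:
            rate_ok = False
            break

    flags: set = set()
    test = session.test_type
    if test in ("IPS", "IPS_DD"):
        if flag_symbol_play_to_quit(session.responses, thresholds):
            flags.add("play_to_quit")
    elif test == "PT":
        if flag_no_touch(session.touch):
            flags.add("no_touch")
    else:
        accel = session.streams["accelerometer"]
        if flag_phone_on_table(accel, thresholds):
            flags.add("phone_on_table")
        if test == "SBT":
            if flag_steps_during_sbt(accel, thresholds):
                flags.add("steps_during_sbt")
        elif test == "UTT":
            if flag_orientation(accel, thresholds):
                flags.add("orientation_unstable")
            turns = _features.detect_turns(session.streams["gyroscope"])
            flags |= flag_utt_insufficient(turns, accel.duration, thresholds)
        elif test == "MWT2":
            if accel.duration <= thresholds.mwt2_min_duration_s:
                flags.add("too_short")
    return QCResult(session_id=session.session_id, test_type=test,
                    rate_ok=rate_ok, rate_detail=detail,
                    flags=frozenset(flags))


def validity_percent(valid: int, total: int) -> float:
    """Validity proportion as a percentage rounded to one decimal."""
    if total == 0:
        raise SchemaError("validity percentage of an empty set")
    return round(100.0 * valid / total, 1)


def summarize_validity(results: Iterable[QCResult]):
    """Per-test validity proportions plus the overall rate-check rate."""
    import pandas as pd

    results = list(results)
    if not results:
        raise SchemaError("no QC results to summarize")
    rows = []
    for test in sorted({r.test_type for r in results}):
        sub = [r for r in results if r.test_type == test]
        valid = sum(r.valid for r in sub)
        rows.append({"test_type": test, "valid": valid, "total": len(sub),
                     "percent_valid": validity_percent(valid, len(sub))})
    per_test = pd.DataFrame(rows)
    rate_ok = sum(r.rate_ok for r in results)
    return {"per_test": per_test,
            "rate_ok_percent": validity_percent(rate_ok, len(results)),
            "rate_ok": rate_ok, "total": len(results)}
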