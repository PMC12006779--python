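"""Test-performance features from raw sensor streams.

One scalar per test: correct responses (processing-speed tests),
successful pinches (pinching test), sway path (static balance), mean
turn speed (U-turn test) and step count (2-minute walk). The detectors
are intentionally simple — band-pass peak counting for steps, yaw-rate
thresholding for turns, pointer-distance closure for pinches — because
the contract they must satisfy is exact recovery of the generator's
ground truth, not clinical validity.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .types import (
    FEATURE_NAME,
    FeatureValue,
    ResponseLog,
    SchemaError,
    SensorSession,
    SensorStream,
    TouchEventLog,
    Turn,
)

log = logging.getLogger(__name__)

#: Turn detection: onset threshold on |yaw rate| and merge hysteresis.
TURN_ONSET_RAD_S = 0.3
TURN_MERGE_GAP_S = 0.2

#: A successful pinch must shrink the inter-pointer distance by at least
#: this fraction between first co-touch and release.
PINCH_CLOSURE_FRACTION = 0.3

#: Step detection band (Hz) and minimum inter-step interval (s).
STEP_BAND_HZ = (0.5, 3.0)
STEP_MIN_INTERVAL_S = 0.25
#: Absolute floor on step-peak height (m/s^2); rejects stance noise.
STEP_MIN_HEIGHT = 0.5

#: Gravity estimate: zero-phase low-pass below the gait band.
GRAVITY_CUTOFF_HZ = 0.5


class InvalidSessionError(ValueError):
    """Feature requested for a session that failed quality control."""


def gravity_component(stream: SensorStream,
                      cutoff_hz: float = GRAVITY_CUTOFF_HZ) -> np.ndarray:
    """Per-axis low-pass gravity estimate (zero-phase 4th-order filter)."""
    fs = stream.mean_rate
    if stream.t.size < 30 or cutoff_hz >= fs / 2:
        return np.tile(stream.xyz.mean(axis=0), (stream.t.size, 1))
    b, a = butter(4, cutoff_hz, fs=fs, btype="low")
    return filtfilt(b, a, stream.xyz, axis=0)


def count_correct_responses(responses: ResponseLog,
                            window: Optional[float] = None) -> int:
    """Responses whose selected digit matches the key's mapping.

    The generator encodes the symbol-digit key by index: ``symK`` maps to
    ``digK``. Entries timestamped outside the test window are excluded
    with a warning.
    """
    if len(responses) == 0:
        return 0
    t = responses.t
    keep = np.ones(t.size, dtype=bool)
    if window is not None:
        keep = (t >= 0) & (t <= window)
        if not keep.all():
            warnings.warn(f"{int((~keep).sum())} responses outside the "
                          "test window were excluded", stacklevel=2)
    shown = responses.shown[keep]
    selected = responses.selected[keep]
    correct = sum(1 for s, d in zip(shown, selected)
                  if s.removeprefix("sym") == d.removeprefix("dig"))
    return int(correct)


def count_pinches(touch: TouchEventLog,
                  closure_fraction: float = PINCH_CLOSURE_FRACTION) -> int:
    """Completed two-pointer gestures that closed by >= closure_fraction.

    Pointer tracks are paired by temporal overlap; each overlapping pair
    is counted at most once. Malformed pointer sequences are skipped
    with a warning rather than failing the session.
    """
    if len(touch) == 0:
        return 0
    tracks = {}
    order = np.argsort(touch.t, kind="stable")
    for i in order:
        pid = int(touch.pointer_id[i])
        kind = touch.kind[i]
        if kind == "down":
            tracks.setdefault(pid, []).append(
                {"t": [touch.t[i]], "x": [touch.x[i]], "y": [touch.y[i]],
                 "open": True})
        else:
            trks = tracks.get(pid)
            if not trks or not trks[-1]["open"]:
                warnings.warn(f"pointer {pid}: {kind} without down; "
                              "skipped", stacklevel=2)
                continue
            trk = trks[-1]
            trk["t"].append(touch.t[i])
            trk["x"].append(touch.x[i])
            trk["y"].append(touch.y[i])
            if kind == "up":
                trk["open"] = False

    gestures = []
    for pid, trks in tracks.items():
        for trk in trks:
            if trk["open"]:
                warnings.warn(f"pointer {pid}: track never lifted; skipped",
                              stacklevel=2)
                continue
            gestures.append((pid, np.asarray(trk["t"]), np.asarray(trk["x"]),
                             np.asarray(trk["y"])))
    gestures.sort(key=lambda g: g[1][0])

    count = 0
    used = [False] * len(gestures)
    for i in range(len(gestures)):
        if used[i]:
            continue
        for j in range(i + 1, len(gestures)):
            if used[j]:
                continue
            ti, tj = gestures[i][1], gestures[j][1]
            lo, hi = max(ti[0], tj[0]), min(ti[-1], tj[-1])
            if lo >= hi:
                continue
            # distance at first co-touch vs release of the pair
            grid = np.array([lo, hi])
            xi = np.interp(grid, ti, gestures[i][2])
            yi = np.interp(grid, ti, gestures[i][3])
            xj = np.interp(grid, tj, gestures[j][2])
            yj = np.interp(grid, tj, gestures[j][3])
            dist = np.hypot(xi - xj, yi - yj)
            if dist[0] > 0 and dist[1] <= (1 - closure_fraction) * dist[0]:
                count += 1
                used[i] = used[j] = True
                break
    return count


def compute_sway_path(accel: SensorStream) -> float:
    """Total path length of the gravity-removed acceleration trajectory.

    Sum over consecutive samples of the Euclidean norm of the change in
    the 3-axis acceleration vector after subtracting the low-pass
    gravity component; units m/s^2. Not normalized by test duration.
    """
    if accel.t.size < 2:
        raise SchemaError("sway path needs at least 2 samples")
    residual = accel.xyz - gravity_component(accel)
    steps = np.linalg.norm(np.diff(residual, axis=0), axis=1)
    return float(steps.sum())


def detect_turns(gyro: SensorStream,
                 onset_rad_s: float = TURN_ONSET_RAD_S,
                 merge_gap_s: float = TURN_MERGE_GAP_S) -> list[Turn]:
    """Segment yaw-rate episodes above the onset threshold into turns.

    Contiguous runs of |yaw| > onset are found, runs separated by less
    than the hysteresis gap are merged, and each segment's angle is the
    trapezoidal integral of the yaw rate over its span.
    """
    if gyro.sensor != "gyroscope":
        raise SchemaError("turn detection requires a gyroscope stream")
    t, yaw = gyro.t, gyro.xyz[:, 2]
    active = np.abs(yaw) > onset_rad_s
    if not active.any():
        return []
    edges = np.diff(active.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(t.size)
    # hysteresis: merge segments separated by a sub-threshold dip shorter
    # than the merge gap
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if t[s] - t[merged[-1][1] - 1] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    turns = []
    for s, e in merged:
        if e - s < 2:
            continue
        # extend to the adjacent sub-threshold samples so the partial
        # edge intervals of the turn are integrated too
        s, e = max(s - 1, 0), min(e + 1, t.size)
        seg_t, seg_y = t[s:e], yaw[s:e]
        angle = float(np.trapezoid(seg_y, seg_t))
        duration = float(seg_t[-1] - seg_t[0])
        turns.append(Turn(start=float(seg_t[0]), end=float(seg_t[-1]),
                          angle_deg=abs(np.rad2deg(angle)),
                          mean_rate=abs(angle) / duration))
    return turns


def turn_speed(turns: list[Turn]) -> float:
    """Mean of per-turn mean yaw rates (rad/s)."""
    if not turns:
        raise SchemaError("turn speed is undefined without turns; "
                          "quality control must run first")
    return float(np.mean([tr.mean_rate for tr in turns]))


def count_steps(accel: SensorStream,
                band_hz: tuple = STEP_BAND_HZ,
                min_interval_s: float = STEP_MIN_INTERVAL_S,
                min_height: float = STEP_MIN_HEIGHT) -> int:
    """Band-pass peak counting on the acceleration magnitude.

    The magnitude is band-passed to the gait band and peaks above an
    adaptive threshold (half the envelope SD, floored at ``min_height``
    so stance noise never registers) are counted, enforcing a minimum
    inter-peak interval.
    """
    if accel.t.size < 2:
        raise SchemaError("step counting needs at least 2 samples")
    fs = accel.mean_rate
    mag = np.linalg.norm(accel.xyz, axis=1)
    mag = mag - mag.mean()
    if fs / 2 <= band_hz[1] or accel.t.size < 30:
        filtered = mag
    else:
        b, a = butter(2, band_hz, fs=fs, btype="band")
        filtered = filtfilt(b, a, mag)
    height = max(min_height, 0.5 * float(np.std(filtered)))
    distance = max(1, int(round(min_interval_s * fs)))
    peaks, _ = find_peaks(filtered, height=height, distance=distance)
    return int(peaks.size)


def extract(session: SensorSession, qc) -> FeatureValue:
    """Dispatch to the feature matching the session's test type.

    Features exist only for sessions that passed quality control;
    passing an invalid session raises :class:`InvalidSessionError`.
    """
    if qc is not None and not qc.valid:
        raise InvalidSessionError(
            f"session {session.session_id} failed quality control "
            f"(flags={sorted(qc.flags)})")
    test = session.test_type
    if test in ("IPS", "IPS_DD"):
        value = count_correct_responses(session.responses,
                                        window=session.nominal_duration)
    elif test == "PT":
        value = count_pinches(session.touch)
    elif test == "SBT":
        value = compute_sway_path(session.streams["accelerometer"])
    elif test == "UTT":
        value = turn_speed(detect_turns(session.streams["gyroscope"]))
    elif test == "MWT2":
        value = count_steps(session.streams["accelerometer"])
    else:  # pragma: no cover - guarded by SensorSession
        raise SchemaError(f"unknown test {test!r}")
    return FeatureValue(
        participant_id=session.participant_id,
        session_id=session.session_id,
        test_type=test,
        feature_name=FEATURE_NAME[test],
        value=float(value),
    )
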