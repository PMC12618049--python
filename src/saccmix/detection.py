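"""Saccade detection from gaze traces and trial-level artifact rejection.

Detection follows the classic amplitude/velocity/acceleration conjunction:
candidate events are maximal runs of samples whose smoothed speed exceeds the
velocity threshold (default 22 deg/s); runs separated by less than
``merge_gap`` ms of valid samples are merged; a candidate is kept iff its
peak absolute acceleration exceeds the acceleration threshold (default
3,800 deg/s^2) and its start-to-end displacement exceeds the amplitude
threshold (default 1 deg).  Velocity is the only samplewise criterion;
amplitude and acceleration act as event-level filters.

Derivatives use a Savitzky-Golay polynomial window (order 2, derivative 1).
The default half-width is 5 samples (11-point window, ~22 ms at 500 Hz):
wide enough that position noise of ~0.1 deg RMS leaves the per-axis velocity
noise floor well below the 22 deg/s threshold, short enough that the peak
velocity of a 20 ms saccade is barely attenuated.  Samples within one
half-width of an invalid gap carry no kinematic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import GazeTrace, TrialRecord


@dataclass(frozen=True)
class DetectionCriteria:
    min_amplitude: float = 1.0       # deg, start->end displacement
    min_velocity: float = 22.0       # deg/s, samplewise threshold
    min_acceleration: float = 3800.0  # deg/s^2, event peak filter
    smoothing_halfwidth: int = 5     # samples; window = 2*hw + 1
    merge_gap: float = 20.0          # ms

    def __post_init__(self) -> None:
        if min(self.min_amplitude, self.min_velocity, self.min_acceleration) <= 0:
            raise ValueError("all detection thresholds must be positive")
        if self.smoothing_halfwidth < 1:
            raise ValueError("smoothing_halfwidth must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass(frozen=True)
class SaccadeEvent:
    onset_time: float    # ms, trial clock
    offset_time: float   # ms
    start_x: float       # deg
    start_y: float
    end_x: float
    end_y: float
    amplitude: float       # deg, Euclidean start->end displacement
    peak_velocity: float   # deg/s
    peak_acceleration: float  # deg/s^2

    def __post_init__(self) -> None:
        if self.offset_time <= self.onset_time:
            raise ValueError("offset_time must exceed onset_time")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class Kinematics:
    """Per-sample speed and acceleration derived from a trace."""

    times: np.ndarray
    speed: np.ndarray      # deg/s; NaN where invalid
    accel: np.ndarray      # deg/s^2; NaN where invalid
    valid: np.ndarray      # bool


ARTIFACT_EXCESS_INVALID = "excess_invalid_fraction"
ARTIFACT_LONG_BLINK = "long_blink"
ARTIFACT_DISCONTINUITY = "discontinuity"
ARTIFACT_DRIFT = "drift"


@dataclass(frozen=True)
class ArtifactRules:
    max_invalid_fraction: float = 0.20
    max_gap_ms: float = 500.0
    max_drift_deg: float = 3.0
    # Maximum plausible displacement between adjacent valid samples (deg);
    # ~1.6 deg/sample corresponds to an 800 deg/s saccade at 500 Hz, so 3 deg
    # flags tracker glitches rather than real movements.
    max_jump_deg: float = 3.0


@dataclass(frozen=True)
class ArtifactReport:
    trial_id: int
    rejected: bool
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.rejected != bool(self.reasons):
            raise ValueError("rejected must match non-empty reasons")


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def differentiate_trace(
    trace: "GazeTrace", criteria: Optional[DetectionCriteria] = None
) -> Kinematics:
    """Smoothed speed and acceleration per sample.

    Speed is the magnitude of the Savitzky-Golay first derivative of (x, y);
    acceleration is the same derivative applied to speed.  Valid runs shorter
    than the smoothing window yield no values, and samples within one
    half-width of an invalid gap are marked invalid.
    """
    criteria = criteria or DetectionCriteria()
    hw = criteria.smoothing_halfwidth
    window = 2 * hw + 1
    valid = np.asarray(trace.valid, dtype=bool)
    if int(valid.sum()) < 2 * hw + 2:
        raise ValueError(
            f"trace has {int(valid.sum())} valid samples; need at least {2 * hw + 2}"
        )
    times = np.asarray(trace.times, dtype=float)
    dt_s = (times[1] - times[0]) / 1000.0
    n = times.size
    speed = np.full(n, np.nan)
    accel = np.full(n, np.nan)
    kin_valid = np.zeros(n, dtype=bool)
    for start, stop in _valid_runs(valid):
        if stop - start < window:
            continue
        vx = savgol_filter(trace.x[start:stop], window, 2, deriv=1, delta=dt_s)
        vy = savgol_filter(trace.y[start:stop], window, 2, deriv=1, delta=dt_s)
        sp = np.hypot(vx, vy)
        ac = savgol_filter(sp, window, 2, deriv=1, delta=dt_s)
        speed[start:stop] = sp
        accel[start:stop] = ac
        kin_valid[start:stop] = True
        # trim the half-width shoulder against each invalid gap (not against
        # the trace boundary, where the polynomial edge fit is still defined)
        if start > 0:
            kin_valid[start:start + hw] = False
            speed[start:start + hw] = np.nan
            accel[start:start + hw] = np.nan
        if stop < n:
            kin_valid[stop - hw:stop] = False
            speed[stop - hw:stop] = np.nan
            accel[stop - hw:stop] = np.nan
    return Kinematics(times=times, speed=speed, accel=accel, valid=kin_valid)


def detect_saccades(
    trace: "GazeTrace", criteria: Optional[DetectionCriteria] = None
) -> list[SaccadeEvent]:
    """Detect saccades in one trace; empty list when nothing qualifies."""
    criteria = criteria or DetectionCriteria()
    kin = differentiate_trace(trace, criteria)
    times = kin.times
    mask = kin.valid & (kin.speed > criteria.min_velocity)
    runs = _valid_runs(mask)
    if not runs:
        return []
    # merge runs separated by a short, fully valid gap
    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        prev = merged[-1]
        gap_ms = times[start] - times[prev[1] - 1]
        if gap_ms < criteria.merge_gap and kin.valid[prev[1]:start].all():
            prev[1] = stop
        else:
            merged.append([start, stop])
    events: list[SaccadeEvent] = []
    for start, stop in merged:
        i, j = start, stop - 1
        peak_acc = float(np.nanmax(np.abs(kin.accel[i:j + 1])))
        disp = float(np.hypot(trace.x[j] - trace.x[i], trace.y[j] - trace.y[i]))
        if peak_acc > criteria.min_acceleration and disp > criteria.min_amplitude:
            events.append(
                SaccadeEvent(
                    onset_time=float(times[i]),
                    offset_time=float(times[j]),
                    start_x=float(trace.x[i]),
                    start_y=float(trace.y[i]),
                    end_x=float(trace.x[j]),
                    end_y=float(trace.y[j]),
                    amplitude=disp,
                    peak_velocity=float(np.nanmax(kin.speed[i:j + 1])),
                    peak_acceleration=peak_acc,
                )
            )
    return events


def reject_artifact_trials(
    trials_with_traces: Iterable[tuple["TrialRecord", "GazeTrace"]],
    rules: Optional[ArtifactRules] = None,
) -> list[ArtifactReport]:
    """Apply trial-level quality rules; each report lists every reason hit.

    A trial is rejected when its invalid-sample fraction exceeds 20%, any
    single invalid gap exceeds 500 ms, adjacent valid samples jump further
    than physiologically plausible (discontinuity), or the median fixation
    position before WS offset drifts more than 3 deg from the fixation cross.
    """
    rules = rules or ArtifactRules()
    reports = []
    for trial, trace in trials_with_traces:
        reasons = []
        valid = np.asarray(trace.valid, dtype=bool)
        times = np.asarray(trace.times, dtype=float)
        dt = times[1] - times[0]
        frac_invalid = 1.0 - valid.mean()
        if frac_invalid > rules.max_invalid_fraction:
            reasons.append(ARTIFACT_EXCESS_INVALID)
        for start, stop in _valid_runs(~valid):
            if (stop - start) * dt > rules.max_gap_ms:
                reasons.append(ARTIFACT_LONG_BLINK)
                break
        vidx = np.flatnonzero(valid)
        if vidx.size >= 2:
            step = np.diff(vidx) == 1  # adjacent valid sample pairs
            jumps = np.hypot(np.diff(trace.x[vidx]),
                             np.diff(trace.y[vidx]))[step]
            if jumps.size and np.nanmax(jumps) > rules.max_jump_deg:
                reasons.append(ARTIFACT_DISCONTINUITY)
        pre = valid & (times < trial.ws_offset_time)
        if pre.any():
            mx = float(np.median(trace.x[pre]))
            my = float(np.median(trace.y[pre]))
            if np.hypot(mx, my) > rules.max_drift_deg:
                reasons.append(ARTIFACT_DRIFT)
        reports.append(
            ArtifactReport(
                trial_id=trial.trial_id,
                rejected=bool(reasons),
                reasons=tuple(reasons),
            )
        )
    return reports
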