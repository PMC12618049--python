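"""Latency-window classification of detected saccades.

Saccades are timed on the trial clock and referenced to the offset of the
warning stimulus (WS), which starts the foreperiod (FP).  A saccade launched
between FP onset and 100 ms after the "go" signal is *early*: it cannot be a
visual response to the target.  A saccade with latency at or beyond
``FP + 100`` ms is a visually guided (VG) candidate; VG candidates are
discarded when they arrive more than 1,000 ms after the go signal, follow an
earlier early saccade, land outside the trial's target box, or follow an
already-accepted VG saccade.  Early saccades are optionally split into a
short-latency (impulsive, "first") and a long-latency (anticipatory,
"second") mode by a latency threshold, normally the mixture crossing point
computed per FP block.

Boundary conventions (closed choices, exercised in tests): latency exactly 0
is early; latency exactly ``FP + 100`` is a VG candidate; the box hit test
uses the closed rectangle, so an endpoint exactly on the box edge counts as
inside.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .detection import SaccadeEvent
    from .simulate import TrialRecord

CATEGORY_EARLY = "early"
CATEGORY_VG = "visually_guided"
CATEGORY_REJECTED = "rejected"

REASON_PRE_FP = "pre_fp"
REASON_LATENCY_OVER_1000 = "latency_over_1000"
REASON_AFTER_EARLY = "after_early"
REASON_WRONG_BOX = "wrong_box"
# Not part of the canonical reason set: labels VG candidates that follow an
# already-accepted VG saccade (at most one VG survives per trial).
REASON_AFTER_VG = "after_vg"

MODE_FIRST = "first"
MODE_SECOND = "second"

#: Grace window after go onset during which a saccade still counts as early
#: (it cannot be a visual response to the target), in ms.
POST_GO_GRACE_MS = 100.0

#: VG saccades with latency beyond this many ms after the go signal are
#: discarded as non-responses.
VG_MAX_LATENCY_AFTER_GO_MS = 1000.0


@dataclass(frozen=True)
class BoxGeometry:
    """Positions and size of the four eccentric target boxes, in degrees.

    The fixation cross sits at the origin at the bottom of the screen; the
    boxes are arranged along an arc roughly 17 deg eccentric from fixation.
    """

    centers: tuple[tuple[float, float], ...]
    width: float = 5.7
    height: float = 4.3

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box width and height must be positive")
        if not self.centers:
            raise ValueError("geometry needs at least one box center")

    @classmethod
    def default(cls, eccentricity: float = 17.0) -> "BoxGeometry":
        """Four boxes on a 17-deg arc above fixation, spread horizontally."""
        xs = (-10.5, -3.5, 3.5, 10.5)
        centers = tuple(
            (x, math.sqrt(eccentricity**2 - x**2)) for x in xs
        )
        return cls(centers=centers)

    @property
    def n_boxes(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class ClassifiedSaccade:
    """A detected saccade with its trial-clock latency and category."""

    event: "SaccadeEvent"
    latency: float
    category: str
    rejection_reason: Optional[str] = None
    mode: Optional[str] = None
    landed_box: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode is not None and self.category != CATEGORY_EARLY:
            raise ValueError("mode may only be set on early saccades")


def compute_latency(event: "SaccadeEvent", trial: "TrialRecord") -> float:
    """Latency of *event* from FP onset (= WS offset), in ms.

    Negative values mark movements launched before the foreperiod started;
    those are categorized as rejected/pre_fp downstream.
    """
    return event.onset_time - trial.ws_offset_time


def box_hit(
    end_x: float, end_y: float, box_index: int, geometry: BoxGeometry
) -> bool:
    """True iff the endpoint lies inside the closed rectangle of the box."""
    if not 0 <= box_index < geometry.n_boxes:
        raise IndexError(f"box_index {box_index} out of range")
    cx, cy = geometry.centers[box_index]
    return (
        abs(end_x - cx) <= geometry.width / 2.0
        and abs(end_y - cy) <= geometry.height / 2.0
    )


def landed_box_index(
    end_x: float, end_y: float, geometry: BoxGeometry
) -> Optional[int]:
    """Index of the first box containing the endpoint, or None."""
    for i in range(geometry.n_boxes):
        if box_hit(end_x, end_y, i, geometry):
            return i
    return None


def assign_mode(latency: float, threshold_ms: float) -> str:
    """First mode strictly below the threshold, second mode at or above."""
    return MODE_FIRST if latency < threshold_ms else MODE_SECOND


def classify_events(
    trial: "TrialRecord",
    events: Sequence["SaccadeEvent"],
    geometry: Optional[BoxGeometry] = None,
    threshold_ms: Optional[float] = None,
) -> list[ClassifiedSaccade]:
    """Classify the time-sorted saccades of one trial.

    Windows on the FP-onset clock (FP = trial.block_fp):

    * latency < 0                      -> rejected / pre_fp
    * 0 <= latency < FP + 100          -> early (mode set when threshold given)
    * latency >= FP + 100              -> VG candidate, then rejected when
      latency - FP > 1000 (latency_over_1000), when any earlier saccade in the
      trial was early (after_early), when the endpoint misses the trial's
      target box (wrong_box), or when a VG saccade already survived
      (after_vg).  At most one VG saccade survives per trial.
    """
    geometry = geometry or BoxGeometry.default()
    fp = trial.block_fp
    ordered = sorted(events, key=lambda e: e.onset_time)
    out: list[ClassifiedSaccade] = []
    seen_early = False
    vg_taken = False
    for ev in ordered:
        lat = compute_latency(ev, trial)
        landed = landed_box_index(ev.end_x, ev.end_y, geometry)
        if lat < 0:
            out.append(
                ClassifiedSaccade(ev, lat, CATEGORY_REJECTED, REASON_PRE_FP,
                                  landed_box=landed)
            )
            continue
        if lat < fp + POST_GO_GRACE_MS:
            mode = assign_mode(lat, threshold_ms) if threshold_ms is not None else None
            out.append(
                ClassifiedSaccade(ev, lat, CATEGORY_EARLY, mode=mode,
                                  landed_box=landed)
            )
            seen_early = True
            continue
        # VG candidate
        if lat - fp > VG_MAX_LATENCY_AFTER_GO_MS:
            reason = REASON_LATENCY_OVER_1000
        elif seen_early:
            reason = REASON_AFTER_EARLY
        elif not box_hit(ev.end_x, ev.end_y, trial.target_box_index, geometry):
            reason = REASON_WRONG_BOX
        elif vg_taken:
            reason = REASON_AFTER_VG
        else:
            out.append(
                ClassifiedSaccade(ev, lat, CATEGORY_VG, landed_box=landed)
            )
            vg_taken = True
            continue
        out.append(
            ClassifiedSaccade(ev, lat, CATEGORY_REJECTED, reason,
                              landed_box=landed)
        )
    return out


def boundary_rule_audit(classified: pd.DataFrame) -> dict:
    """Tally categories and rejection reasons over a classified table.

    Expects columns ``trial_id``, ``category`` and ``rejection_reason``; rows
    are individual classified saccades.  ``n_trials`` may exceed the number
    of trial ids present (trials without any saccade row still count in the
    denominators) when passed explicitly via the attribute
    ``classified.attrs["n_trials"]``; otherwise the number of distinct trial
    ids is used.

    Returns a plain dict with per-category counts, per-reason counts, the
    fraction of trials with at least one early saccade, the fraction of
    trials with a surviving VG saccade, and the number of trials holding more
    than one early saccade (flagged, not discarded).
    """
    if len(classified) == 0:
        n_trials = int(classified.attrs.get("n_trials", 0))
        return {
            "n_trials": n_trials,
            "n_saccades": 0,
            "category_counts": {},
            "reason_counts": {},
            "early_trial_fraction": 0.0,
            "vg_trial_fraction": 0.0,
            "multi_early_trials": 0,
        }
    n_trials = int(classified.attrs.get(
        "n_trials", classified["trial_id"].nunique()
    ))
    cat_counts = Counter(classified["category"])
    reason_counts = Counter(
        r for r in classified["rejection_reason"] if isinstance(r, str)
    )
    early = classified[classified["category"] == CATEGORY_EARLY]
    early_per_trial = early.groupby("trial_id").size()
    vg = classified[classified["category"] == CATEGORY_VG]
    return {
        "n_trials": n_trials,
        "n_saccades": int(len(classified)),
        "category_counts": dict(cat_counts),
        "reason_counts": dict(reason_counts),
        "early_trial_fraction": float(len(early_per_trial) / n_trials)
        if n_trials else 0.0,
        "vg_trial_fraction": float(vg["trial_id"].nunique() / n_trials)
        if n_trials else 0.0,
        "multi_early_trials": int((early_per_trial > 1).sum()),
    }


def classified_frame(
    trial: "TrialRecord", classified: Iterable[ClassifiedSaccade]
) -> pd.DataFrame:
    """One-trial classified saccades as a tidy table."""
    rows = []
    for c in classified:
        rows.append(
            {
                "trial_id": trial.trial_id,
                "subject": trial.subject_id,
                "fp": trial.block_fp,
                "su": trial.su_level,
                "latency": c.latency,
                "category": c.category,
                "rejection_reason": c.rejection_reason,
                "mode": c.mode,
                "landed_box": c.landed_box,
                "amplitude": c.event.amplitude,
                "vmax": c.event.peak_velocity,
                "onset_ms": c.event.onset_time,
                "offset_ms": c.event.offset_time,
                "end_x": c.event.end_x,
                "end_y": c.event.end_y,
            }
        )
    return pd.DataFrame(rows)
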