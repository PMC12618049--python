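"""Readers and writers binding the pipeline stages into reproducible runs.

All tables are UTF-8 tab-separated values with a header row; the trial clock
is milliseconds from trial start and all angles are degrees of visual angle.
Config files are flat YAML mirroring the dataclass fields; unknown keys are
rejected so a typo cannot silently fall back to a default.  A run manifest
(JSON: config hash, seed, package version) makes any report reproducible
from config + seed alone.

``parse_ascii_samples`` reads a minimal eye-tracker ASCII sample dialect:
tab-separated ``timestamp  x_px  y_px  pupil`` lines with ``.`` marking
missing samples, and ``MSG <t> TRIALID <id>`` lines delimiting trials.
Pixels become degrees through a per-axis arctangent about the screen center
(not a flat pixels-per-degree constant), so eccentric samples are not
inflated.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import BoxGeometry
from .detection import SaccadeEvent
from .simulate import (
    GazeTrace,
    GroundTruthSaccade,
    SimulationConfig,
    TrialRecord,
    config_from_dict,
    config_to_dict,
    trials_frame,
    truth_frame,
)

FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class ScreenGeometry:
    """Monitor geometry for pixel-to-degree conversion."""

    distance_cm: float = 80.0
    width_cm: float = 54.0
    height_cm: float = 30.0
    width_px: int = 1920
    height_px: int = 1080

    def px_to_deg(self, x_px: np.ndarray, y_px: np.ndarray):
        """Per-axis arctangent conversion about the screen center."""
        dx_cm = (np.asarray(x_px, float) - self.width_px / 2.0) \
            * self.width_cm / self.width_px
        dy_cm = (self.height_px / 2.0 - np.asarray(y_px, float)) \
            * self.height_cm / self.height_px  # screen y grows downward
        x_deg = np.degrees(np.arctan2(dx_cm, self.distance_cm))
        y_deg = np.degrees(np.arctan2(dy_cm, self.distance_cm))
        return x_deg, y_deg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_trials(trials: Sequence[TrialRecord], outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(trials_frame(trials), outdir / "trials.tsv")
    _write_tsv(truth_frame(trials), outdir / "truth.tsv")


def read_trials(indir: Path) -> list[TrialRecord]:
    indir = Path(indir)
    tdf = pd.read_csv(indir / "trials.tsv", sep="\t")
    truth_path = indir / "truth.tsv"
    truth_by_trial: dict[int, list[GroundTruthSaccade]] = {}
    if truth_path.exists():
        gdf = pd.read_csv(truth_path, sep="\t")
        for _, r in gdf.iterrows():
            truth_by_trial.setdefault(int(r["trial_id"]), []).append(
                GroundTruthSaccade(
                    process=r["process"],
                    latency_from_fp_onset=float(r["latency_ms"]),
                    amplitude=float(r["amplitude_deg"]),
                    peak_velocity=float(r["vmax_deg_s"]),
                    target_box_index=int(r["target_box"]),
                    end_x=float(r["end_x_deg"]),
                    end_y=float(r["end_y_deg"]),
                )
            )
    trials = []
    for _, r in tdf.iterrows():
        tid = int(r["trial_id"])
        cued = frozenset(int(v) for v in str(r["cued_boxes"]).split(","))
        trials.append(TrialRecord(
            trial_id=tid,
            subject_id=int(r["subject"]),
            block_fp=float(r["fp"]),
            su_level=int(r["su"]),
            cued_box_indices=cued,
            ws_offset_time=float(r["ws_offset_ms"]),
            go_onset_time=float(r["go_onset_ms"]),
            target_box_index=int(r["target_box"]),
            truth=tuple(truth_by_trial.get(tid, ())) or None,
        ))
    return trials


def write_traces(traces: dict, path: Path) -> None:
    """Packed samples file: trial_id, time_ms, x_deg, y_deg, valid."""
    frames = []
    for tid, tr in traces.items():
        frames.append(pd.DataFrame({
            "trial_id": tid,
            "time_ms": tr.times,
            "x_deg": tr.x,
            "y_deg": tr.y,
            "valid": tr.valid.astype(int),
        }))
    _write_tsv(pd.concat(frames, ignore_index=True), Path(path))


def read_traces(path: Path) -> dict:
    df = pd.read_csv(Path(path), sep="\t")
    out = {}
    for tid, g in df.groupby("trial_id"):
        out[int(tid)] = GazeTrace(
            times=g["time_ms"].to_numpy(dtype=float),
            x=g["x_deg"].to_numpy(dtype=float),
            y=g["y_deg"].to_numpy(dtype=float),
            valid=g["valid"].to_numpy(dtype=bool),
        )
    return out


EVENT_COLUMNS = [
    "trial_id", "onset_ms", "offset_ms", "start_x_deg", "start_y_deg",
    "end_x_deg", "end_y_deg", "amplitude_deg", "vmax_deg_s",
    "peak_accel_deg_s2",
]


def write_events(events_by_trial: dict, path: Path) -> None:
    rows = []
    for tid, events in events_by_trial.items():
        for e in events:
            rows.append([tid, e.onset_time, e.offset_time, e.start_x,
                         e.start_y, e.end_x, e.end_y, e.amplitude,
                         e.peak_velocity, e.peak_acceleration])
    _write_tsv(pd.DataFrame(rows, columns=EVENT_COLUMNS), Path(path))


def read_events(path: Path) -> dict:
    df = pd.read_csv(Path(path), sep="\t")
    out: dict[int, list[SaccadeEvent]] = {}
    for _, r in df.iterrows():
        out.setdefault(int(r["trial_id"]), []).append(SaccadeEvent(
            onset_time=float(r["onset_ms"]),
            offset_time=float(r["offset_ms"]),
            start_x=float(r["start_x_deg"]),
            start_y=float(r["start_y_deg"]),
            end_x=float(r["end_x_deg"]),
            end_y=float(r["end_y_deg"]),
            amplitude=float(r["amplitude_deg"]),
            peak_velocity=float(r["vmax_deg_s"]),
            peak_acceleration=float(r["peak_accel_deg_s2"]),
        ))
    return out


def write_classified(df: pd.DataFrame, path: Path) -> None:
    _write_tsv(df, Path(path))


def read_classified(path: Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def load_simulation_config(path: Path) -> SimulationConfig:
    """Strict YAML load: unknown keys raise instead of being ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    return config_from_dict(data)


def save_simulation_config(config: SimulationConfig, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: SimulationConfig) -> str:
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(config: SimulationConfig, seed: int, outdir: Path,
                   extra: Optional[dict] = None) -> None:
    manifest = {
        "package": "saccmix",
        "version": __version__,
        "seed": int(seed),
        "config_sha256": config_hash(config),
        "config": config_to_dict(config),
    }
    if extra:
        manifest.update(extra)
    with open(Path(outdir) / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def parse_ascii_samples(
    path: Path, geometry: Optional[ScreenGeometry] = None
) -> dict:
    """Parse the minimal ASCII sample dialect into per-trial GazeTraces.

    Trial boundaries come from ``MSG <t> TRIALID <id>`` lines; a sample line
    is ``<timestamp>\\t<x_px>\\t<y_px>\\t<pupil>`` and ``.`` in the gaze
    columns marks a missing sample (invalid, NaN position).  Timestamps are
    rebased so each trial starts at 0 ms.  Malformed lines raise with the
    line number; a missing geometry block raises.
    """
    if geometry is None:
        raise ValueError("a screen geometry block is required")
    path = Path(path)
    raw: dict[int, list[tuple[float, float, float, bool]]] = {}
    current: Optional[int] = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "MSG":
                if len(parts) >= 3 and parts[2].startswith("TRIALID"):
                    try:
                        current = int(parts[2].split()[1])
                    except (IndexError, ValueError) as exc:
                        raise ValueError(
                            f"{path}:{lineno}: malformed TRIALID message"
                        ) from exc
                    raw[current] = []
                continue
            if current is None:
                raise ValueError(
                    f"{path}:{lineno}: sample line before any TRIALID message"
                )
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields"
                )
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad timestamp") from exc
            if parts[1] == "." or parts[2] == ".":
                raw[current].append((t, math.nan, math.nan, False))
                continue
            try:
                xpx, ypx = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad gaze coordinates"
                ) from exc
            raw[current].append((t, xpx, ypx, True))
    traces = {}
    for tid, samples in raw.items():
        if not samples:
            continue
        t0 = samples[0][0]
        times = np.array([s[0] - t0 for s in samples])
        xpx = np.array([s[1] for s in samples])
        ypx = np.array([s[2] for s in samples])
        valid = np.array([s[3] for s in samples], dtype=bool)
        x_deg, y_deg = geometry.px_to_deg(xpx, ypx)
        x_deg[~valid] = np.nan
        y_deg[~valid] = np.nan
        traces[tid] = GazeTrace(times=times, x=x_deg, y=y_deg, valid=valid)
    return traces


def default_geometry() -> BoxGeometry:
    return BoxGeometry.default()
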