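"""Synthetic foreperiod-task experiments with a two-process early-saccade
structure.

The generator emulates a blocked foreperiod (FP) oculomotor task: on each
trial a warning stimulus (WS) offset starts a delay of 400, 900, 1,400 or
1,900 ms (constant within a block), after which a "go" target appears in one
of four eccentric boxes.  A spatial cue sets the number of candidate boxes
(spatial uncertainty levels SU1..SU4, target probabilities 1, 1/2, 1/3, 1/4).
Before the go signal two independent processes can launch an "early"
saccade:

* an **impulsive** process whose latency is normal with an FP-independent
  mean (~200 ms) and whose per-trial occurrence rate decays log-linearly
  with FP (slope -0.001 per ms);
* an **anticipatory** process whose latency mean and SD both grow linearly
  with FP (scalar expectancy; slopes 0.61 ms/ms and 0.17 ms/ms), with a
  per-trial occurrence probability that does not depend on FP.

At most one early saccade fires per trial; the impulsive process is sampled
first and pre-empts the anticipatory one.  Early latencies beyond
``FP + 100`` ms are censored (the trial reverts to a visually-guided-only
trial).  Trials without an early saccade get a visually guided (VG) response
after the go signal.  Saccade kinematics follow the main sequence
``Vmax = V_inf * (1 - exp(-A / A0))`` with an additive peak-velocity bonus
and amplitude bonus for anticipatory saccades.  Per-subject "disinhibition"
is a single lognormal rate multiplier applied to both processes, which
induces the positive between-subject correlation of impulsive and
anticipatory counts.

Raw gaze traces are produced per trial by holding fixation at the origin and
inserting a raised-cosine position ramp per ground-truth saccade; the
profile has the closed-form peak velocity ``(pi / 2) * A / D`` for amplitude
A and duration D, which the detection tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import BoxGeometry
from .detection import SaccadeEvent

PROCESS_IMPULSIVE = "impulsive"
PROCESS_ANTICIPATORY = "anticipatory"
PROCESS_VG = "visually_guided"

#: Censoring margin: an early latency may exceed the foreperiod by at most
#: this many ms (the post-go grace window of the classification rules).
CENSOR_MARGIN_MS = 100.0


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs; defaults are the study conditions.

    Slopes and differences (anticipatory_mu_fp_slope, anticipatory_sigma_fp_
    slope, impulsive_log_rate_fp_slope, mode2_vmax_bonus, mode2_amplitude_
    bonus, su rate ratios) are the reported effect sizes the generator is
    built to reproduce; intercepts and nuisance scales are package
    calibration, documented in docs/methods.md.
    """

    n_subjects: int = 25
    trials_per_block: int = 120
    fp_levels: tuple[float, ...] = (400.0, 900.0, 1400.0, 1900.0)
    su_probabilities: tuple[float, ...] = (1.0, 0.5, 1.0 / 3.0, 0.25)
    sampling_rate: float = 500.0  # Hz

    # impulsive (1st-mode) process
    impulsive_mu: float = 200.0      # ms, FP-independent latency mean
    impulsive_sigma: float = 60.0    # ms
    impulsive_log_rate_intercept: float = math.log(0.1755)
    impulsive_log_rate_fp_slope: float = -0.001  # per ms of FP

    # anticipatory (2nd-mode) process
    anticipatory_rate: float = 0.157  # per-trial occurrence probability
    anticipatory_mu_intercept: float = 196.0  # ms -> mean 440 ms at FP 400
    anticipatory_mu_fp_slope: float = 0.61    # ms per ms of FP
    anticipatory_sigma_intercept: float = 1.0  # ms
    anticipatory_sigma_fp_slope: float = 0.17  # ms per ms of FP

    # spatial uncertainty: rate ratios 1 : 1/3.5 : 1/3.5 : 1/4.5
    su_rate_factors: tuple[float, ...] = (1.0, 2.0 / 7.0, 2.0 / 7.0, 2.0 / 9.0)
    amplitude_by_su: tuple[float, ...] = (13.1, 11.2, 9.9, 10.7)  # deg
    mode2_amplitude_bonus: float = 0.8  # deg
    amplitude_sd: float = 2.0           # deg
    amplitude_floor: float = 1.5        # deg

    # main sequence and peak velocity
    main_sequence_vmax_asymptote: float = 320.0  # deg/s
    main_sequence_amplitude_scale: float = 3.2   # deg
    mode2_vmax_bonus: float = 21.2               # deg/s
    mode2_vmax_fp_slope: float = -0.02           # deg/s per ms (FP-centered)
    vmax_sd: float = 35.0                        # deg/s

    # visually guided response
    vg_latency_mu: float = 200.0     # ms after go
    vg_latency_sigma: float = 50.0   # ms
    vg_latency_floor: float = 105.0  # ms; keeps VG past the grace window
    vg_endpoint_sd: float = 1.35     # deg per axis around the target center

    # subject heterogeneity: lognormal rate multiplier (mean 1)
    subject_rate_sigma_log: float = 0.5

    # raw-trace rendering
    noise_sd: float = 0.05           # deg, additive position noise
    blink_probability: float = 0.05  # per trial
    blink_gap_range: tuple[float, float] = (100.0, 300.0)  # ms
    pre_ws_ms: float = 300.0         # fixation shown before WS offset
    trace_tail_ms: float = 800.0     # recording continues past go onset

    seed: int = 0

    def validate(self) -> None:
        probs = list(self.su_probabilities) + [
            self.anticipatory_rate, self.blink_probability
        ]
        if any(not (0.0 < p <= 1.0) for p in self.su_probabilities):
            raise ValueError("su_probabilities must lie in (0, 1]")
        if not (0.0 <= self.anticipatory_rate <= 1.0):
            raise ValueError("anticipatory_rate must lie in [0, 1]")
        if not (0.0 <= self.blink_probability <= 1.0):
            raise ValueError("blink_probability must lie in [0, 1]")
        if min(self.impulsive_sigma, self.anticipatory_sigma_intercept,
               self.amplitude_sd, self.vg_latency_sigma) <= 0:
            raise ValueError("all SDs must be positive")
        if any(fp <= 0 for fp in self.fp_levels):
            raise ValueError("fp_levels must be strictly positive")
        if self.anticipatory_mu_fp_slope < 0 or self.anticipatory_sigma_fp_slope < 0:
            raise ValueError(
                "anticipatory mu/sigma FP slopes must be non-negative "
                "(scalar expectancy is built in)"
            )
        if not (len(self.su_probabilities) == len(self.su_rate_factors)
                == len(self.amplitude_by_su)):
            raise ValueError(
                "su_probabilities, su_rate_factors and amplitude_by_su "
                "must have equal length"
            )
        if self.trials_per_block % len(self.su_probabilities):
            raise ValueError(
                "trials_per_block must be divisible by the number of SU levels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        _ = probs  # length checks above are the real content


@dataclass(frozen=True)
class GroundTruthSaccade:
    process: str                    # impulsive | anticipatory | visually_guided
    latency_from_fp_onset: float    # ms
    amplitude: float                # deg
    peak_velocity: float            # deg/s
    target_box_index: int
    end_x: float                    # deg, landing point
    end_y: float

    def __post_init__(self) -> None:
        if self.latency_from_fp_onset < 0:
            raise ValueError("latency must be non-negative")
        if self.amplitude <= 0 or self.peak_velocity <= 0:
            raise ValueError("amplitude and peak_velocity must be positive")


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    subject_id: int
    block_fp: float                  # ms
    su_level: int                    # 1..4
    cued_box_indices: frozenset[int]
    ws_offset_time: float            # ms on the trial clock (FP onset)
    go_onset_time: float             # ms (= ws_offset_time + block_fp)
    target_box_index: int
    truth: Optional[tuple[GroundTruthSaccade, ...]] = None

    def __post_init__(self) -> None:
        if len(self.cued_box_indices) != self.su_level:
            raise ValueError("cued box count must equal su_level")
        if self.target_box_index not in self.cued_box_indices:
            raise ValueError("target box must be among the cued boxes")
        if not math.isclose(self.go_onset_time - self.ws_offset_time,
                            self.block_fp):
            raise ValueError("go onset minus WS offset must equal the FP")


@dataclass(frozen=True)
class GazeTrace:
    times: np.ndarray   # ms, uniform
    x: np.ndarray       # deg; NaN where invalid
    y: np.ndarray
    valid: np.ndarray   # bool


def build_default_config(**overrides) -> SimulationConfig:
    """The default study conditions; keyword overrides for what-if runs."""
    cfg = replace(SimulationConfig(), **overrides)
    cfg.validate()
    return cfg


def main_sequence_vmax(amplitude, asymptote: float, scale: float):
    """Saturating amplitude-velocity coupling V_inf * (1 - exp(-A/A0))."""
    return asymptote * (1.0 - np.exp(-np.asarray(amplitude, dtype=float) / scale))


def raised_cosine_duration_ms(amplitude: float, peak_velocity: float) -> float:
    """Duration giving the raised-cosine profile its requested peak velocity.

    The profile s(t) = (A/2)(1 - cos(pi t / D)) has peak velocity
    (pi/2) A / D, so D = pi A / (2 Vmax).
    """
    return math.pi * amplitude / (2.0 * peak_velocity) * 1000.0


def subject_rng(seed: int, subject_id: int) -> np.random.Generator:
    """One named random stream per subject, stable under reordering."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_id,))
    )


def trace_rng(seed: int, trial_id: int) -> np.random.Generator:
    """Per-trial stream for trace rendering, independent of event draws."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1_000_000, trial_id))
    )


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      lower: float) -> float:
    """Rejection-sampled normal draw bounded below (rare tail, cheap)."""
    for _ in range(10_000):
        v = rng.normal(mu, sd)
        if v >= lower:
            return float(v)
    raise RuntimeError("truncated normal sampling failed; check parameters")


def _draw_vmax(rng, config: SimulationConfig, amplitude: float,
               anticipatory: bool, fp: float, fp_center: float) -> float:
    v = float(main_sequence_vmax(
        amplitude, config.main_sequence_vmax_asymptote,
        config.main_sequence_amplitude_scale,
    ))
    if anticipatory:
        v += config.mode2_vmax_bonus
        v += config.mode2_vmax_fp_slope * (fp - fp_center)
    v += rng.normal(0.0, config.vmax_sd)
    return max(v, 50.0)


def generate_experiment(
    config: SimulationConfig, seed: Optional[int] = None,
    geometry: Optional[BoxGeometry] = None,
) -> list[TrialRecord]:
    """Simulate the full experiment; deterministic given (config, seed).

    For each subject the four FP blocks run in a subject-specific random
    order; each block holds ``trials_per_block`` trials balanced over SU
    levels.  Trial-level occurrence probabilities outside [0, 1] (possible
    only with a miscalibrated config) raise ``ValueError``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    geometry = geometry or BoxGeometry.default()
    n_boxes = geometry.n_boxes
    n_su = len(config.su_probabilities)
    fp_center = float(np.mean(config.fp_levels))
    trials: list[TrialRecord] = []
    trial_id = 0
    for s in range(config.n_subjects):
        rng = subject_rng(seed, s)
        mult = math.exp(
            config.subject_rate_sigma_log * rng.standard_normal()
            - 0.5 * config.subject_rate_sigma_log**2
        )
        block_order = rng.permutation(len(config.fp_levels))
        for b in block_order:
            fp = float(config.fp_levels[b])
            su_seq = np.repeat(np.arange(1, n_su + 1),
                               config.trials_per_block // n_su)
            rng.shuffle(su_seq)
            for su in su_seq:
                su = int(su)
                start = int(rng.integers(0, n_boxes - su + 1))
                cued = frozenset(range(start, start + su))
                target = int(rng.choice(sorted(cued)))
                su_factor = config.su_rate_factors[su - 1]
                p_imp = mult * su_factor * math.exp(
                    config.impulsive_log_rate_intercept
                    + config.impulsive_log_rate_fp_slope * fp
                )
                p_ant = mult * su_factor * config.anticipatory_rate
                if not (0.0 <= p_imp <= 1.0 and 0.0 <= p_ant <= 1.0):
                    raise ValueError(
                        f"occurrence probability outside [0, 1] "
                        f"(impulsive {p_imp:.3f}, anticipatory {p_ant:.3f}); "
                        "the config is miscalibrated"
                    )
                early: Optional[tuple[str, float]] = None
                if rng.random() < p_imp:
                    lat = _truncated_normal(
                        rng, config.impulsive_mu, config.impulsive_sigma, 0.0
                    )
                    if lat < fp + CENSOR_MARGIN_MS:
                        early = (PROCESS_IMPULSIVE, lat)
                elif rng.random() < p_ant:
                    mu = (config.anticipatory_mu_intercept
                          + config.anticipatory_mu_fp_slope * fp)
                    sg = (config.anticipatory_sigma_intercept
                          + config.anticipatory_sigma_fp_slope * fp)
                    lat = _truncated_normal(rng, mu, sg, 0.0)
                    if lat < fp + CENSOR_MARGIN_MS:
                        early = (PROCESS_ANTICIPATORY, lat)
                truth: list[GroundTruthSaccade] = []
                cx, cy = geometry.centers[target]
                if early is not None:
                    process, lat = early
                    anticip = process == PROCESS_ANTICIPATORY
                    amp = max(
                        config.amplitude_floor,
                        rng.normal(
                            config.amplitude_by_su[su - 1]
                            + (config.mode2_amplitude_bonus if anticip else 0.0),
                            config.amplitude_sd,
                        ),
                    )
                    ecc = math.hypot(cx, cy)
                    truth.append(GroundTruthSaccade(
                        process=process,
                        latency_from_fp_onset=lat,
                        amplitude=float(amp),
                        peak_velocity=_draw_vmax(
                            rng, config, amp, anticip, fp, fp_center),
                        target_box_index=target,
                        end_x=cx / ecc * amp,
                        end_y=cy / ecc * amp,
                    ))
                else:
                    rt = _truncated_normal(
                        rng, config.vg_latency_mu, config.vg_latency_sigma,
                        config.vg_latency_floor,
                    )
                    ex = cx + rng.normal(0.0, config.vg_endpoint_sd)
                    ey = cy + rng.normal(0.0, config.vg_endpoint_sd)
                    amp = math.hypot(ex, ey)
                    truth.append(GroundTruthSaccade(
                        process=PROCESS_VG,
                        latency_from_fp_onset=fp + rt,
                        amplitude=amp,
                        peak_velocity=_draw_vmax(
                            rng, config, amp, False, fp, fp_center),
                        target_box_index=target,
                        end_x=ex,
                        end_y=ey,
                    ))
                trials.append(TrialRecord(
                    trial_id=trial_id,
                    subject_id=s,
                    block_fp=fp,
                    su_level=su,
                    cued_box_indices=cued,
                    ws_offset_time=config.pre_ws_ms,
                    go_onset_time=config.pre_ws_ms + fp,
                    target_box_index=target,
                    truth=tuple(truth),
                ))
                trial_id += 1
    return trials


def synthesize_trace(
    trial: TrialRecord, config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GazeTrace:
    """Render one trial's gaze trace from its ground-truth events.

    Fixation is held at the origin; each saccade is a raised-cosine position
    ramp toward its landing point, with the profile duration chosen so the
    realized peak velocity equals ``min(truth value, main-sequence bound)``.
    Gaussian position noise (``noise_sd``) is added to valid samples; with
    ``blink_probability`` a contiguous invalid gap is inserted away from the
    saccade intervals.
    """
    if trial.truth is None:
        raise ValueError("trial.truth must be populated")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = 1000.0 / config.sampling_rate
    total = trial.go_onset_time + config.trace_tail_ms
    times = np.arange(0.0, total, dt)
    x = np.zeros_like(times)
    y = np.zeros_like(times)
    valid = np.ones(times.size, dtype=bool)
    cur = (0.0, 0.0)
    saccade_intervals: list[tuple[float, float]] = []
    for g in sorted(trial.truth, key=lambda t: t.latency_from_fp_onset):
        onset = trial.ws_offset_time + g.latency_from_fp_onset
        disp = math.hypot(g.end_x - cur[0], g.end_y - cur[1])
        if disp <= 0:
            continue
        bound = float(main_sequence_vmax(
            disp, config.main_sequence_vmax_asymptote,
            config.main_sequence_amplitude_scale,
        ))
        vpeak = min(g.peak_velocity, bound)
        dur = raised_cosine_duration_ms(disp, vpeak)
        if onset + dur > times[-1]:
            raise ValueError(
                f"saccade at {onset:.0f}+{dur:.0f} ms extends beyond the "
                f"trace end ({times[-1]:.0f} ms)"
            )
        ramp = (times >= onset) & (times <= onset + dur)
        frac = 0.5 * (1.0 - np.cos(math.pi * (times[ramp] - onset) / dur))
        x[ramp] = cur[0] + (g.end_x - cur[0]) * frac
        y[ramp] = cur[1] + (g.end_y - cur[1]) * frac
        after = times > onset + dur
        x[after] = g.end_x
        y[after] = g.end_y
        cur = (g.end_x, g.end_y)
        saccade_intervals.append((onset, onset + dur))
    if rng.random() < config.blink_probability:
        lo, hi = config.blink_gap_range
        length = float(rng.uniform(lo, hi))
        for _ in range(100):
            t0 = float(rng.uniform(0.0, max(total - length, dt)))
            window = (t0, t0 + length)
            if all(window[1] < a or window[0] > b + 10.0
                   for a, b in saccade_intervals):
                valid[(times >= window[0]) & (times <= window[1])] = False
                break
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, times.size)
        y = y + rng.normal(0.0, config.noise_sd, times.size)
    x[~valid] = np.nan
    y[~valid] = np.nan
    return GazeTrace(times=times, x=x, y=y, valid=valid)


def truth_to_events(trial: TrialRecord) -> list[SaccadeEvent]:
    """Ground-truth saccades as idealized detector output.

    Event-level analyses (classification, mixtures, trends) can run directly
    on these without rendering and re-detecting traces; the raw-trace route
    through ``synthesize_trace`` + the detection module is the slower,
    noisier equivalent.
    """
    if trial.truth is None:
        raise ValueError("trial.truth must be populated")
    events = []
    for g in sorted(trial.truth, key=lambda t: t.latency_from_fp_onset):
        onset = trial.ws_offset_time + g.latency_from_fp_onset
        dur = raised_cosine_duration_ms(g.amplitude, g.peak_velocity)
        events.append(SaccadeEvent(
            onset_time=onset,
            offset_time=onset + dur,
            start_x=0.0,
            start_y=0.0,
            end_x=g.end_x,
            end_y=g.end_y,
            amplitude=g.amplitude,
            peak_velocity=g.peak_velocity,
            peak_acceleration=math.pi * g.peak_velocity / (dur / 1000.0),
        ))
    return events


def trials_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial metadata as a tidy table (one row per trial)."""
    return pd.DataFrame([
        {
            "trial_id": t.trial_id,
            "subject": t.subject_id,
            "fp": t.block_fp,
            "su": t.su_level,
            "cued_boxes": ",".join(str(i) for i in sorted(t.cued_box_indices)),
            "ws_offset_ms": t.ws_offset_time,
            "go_onset_ms": t.go_onset_time,
            "target_box": t.target_box_index,
        }
        for t in trials
    ])


def truth_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Ground-truth events as a tidy table (one row per event)."""
    rows = []
    for t in trials:
        for g in t.truth or ():
            rows.append({
                "trial_id": t.trial_id,
                "subject": t.subject_id,
                "fp": t.block_fp,
                "su": t.su_level,
                "process": g.process,
                "latency_ms": g.latency_from_fp_onset,
                "amplitude_deg": g.amplitude,
                "vmax_deg_s": g.peak_velocity,
                "target_box": g.target_box_index,
                "end_x_deg": g.end_x,
                "end_y_deg": g.end_y,
            })
    return pd.DataFrame(rows)


def config_to_dict(config: SimulationConfig) -> dict:
    out = {}
    for f in fields(config):
        v = getattr(config, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
    }
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
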