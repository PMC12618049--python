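"""Detector behavior: kinematic differentiation, threshold conjunction,
recall on generator output, and artifact-rejection rules."""

import math
from dataclasses import replace

import numpy as np
import pytest

from saccmix import (
    ArtifactRules,
    DetectionCriteria,
    build_default_config,
    detect_saccades,
    differentiate_trace,
    generate_experiment,
    reject_artifact_trials,
    synthesize_trace,
)
from saccmix.simulate import (
    GazeTrace,
    GroundTruthSaccade,
    TrialRecord,
    raised_cosine_duration_ms,
    trace_rng,
)


def _trace(x, y, rate=500.0, valid=None):
    n = len(x)
    times = np.arange(n) * 1000.0 / rate
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrace(times=times, x=np.asarray(x, float),
                     y=np.asarray(y, float), valid=np.asarray(valid, bool))


def _raised_cosine_trace(amp, dur_ms, onset_ms=400.0, total_ms=1200.0,
                         rate=500.0, noise=0.0, seed=0):
    times = np.arange(0.0, total_ms, 1000.0 / rate)
    x = np.zeros_like(times)
    ramp = (times >= onset_ms) & (times <= onset_ms + dur_ms)
    x[ramp] = amp * 0.5 * (1 - np.cos(math.pi * (times[ramp] - onset_ms) / dur_ms))
    x[times > onset_ms + dur_ms] = amp
    if noise:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0, noise, times.size)
    return _trace(x, np.zeros_like(x), rate)


def test_differentiate_constant_position_is_zero():
    tr = _trace(np.full(400, 2.0), np.full(400, -1.0))
    kin = differentiate_trace(tr)
    assert np.nanmax(np.abs(kin.speed)) == pytest.approx(0.0, abs=1e-9)
    assert np.nanmax(np.abs(kin.accel)) == pytest.approx(0.0, abs=1e-9)


def test_differentiate_linear_drift_speed():
    t_s = np.arange(500) / 500.0
    tr = _trace(5.0 * t_s, np.zeros_like(t_s))
    kin = differentiate_trace(tr)
    interior = kin.speed[20:-20]
    assert np.nanmax(np.abs(interior - 5.0)) < 0.05


def test_differentiate_raised_cosine_peak_speed_closed_form():
    """Peak speed matches (pi/2) A / D within 3% for profiles inside the
    smoothing window's passband (duration >= ~70 ms; shorter saccades are
    attenuated more, which never threatens the 22 deg/s threshold)."""
    amp, dur = 12.0, 80.0
    tr = _raised_cosine_trace(amp, dur)
    kin = differentiate_trace(tr)
    expected = math.pi / 2 * amp / (dur / 1000.0)
    assert np.nanmax(kin.speed) == pytest.approx(expected, rel=0.03)


def test_differentiate_short_saccade_attenuated_but_detectable():
    amp, dur = 2.0, 25.0
    tr = _raised_cosine_trace(amp, dur)
    kin = differentiate_trace(tr)
    expected = math.pi / 2 * amp / (dur / 1000.0)
    peak = np.nanmax(kin.speed)
    assert peak < expected            # low-pass attenuation
    assert peak > 0.7 * expected      # but the event remains prominent


def test_differentiate_too_few_valid_samples_raises():
    tr = _trace(np.zeros(8), np.zeros(8))
    with pytest.raises(ValueError, match="valid samples"):
        differentiate_trace(tr, DetectionCriteria(smoothing_halfwidth=5))


def test_detect_nothing_on_fixation():
    assert detect_saccades(_trace(np.zeros(600), np.zeros(600))) == []


def test_detect_single_synthetic_saccade_with_noise():
    cfg = replace(build_default_config(), noise_sd=0.15, blink_probability=0.0)
    geom_amp = 13.0
    g = GroundTruthSaccade(
        process="visually_guided", latency_from_fp_onset=600.0,
        amplitude=geom_amp, peak_velocity=290.0, target_box_index=0,
        end_x=geom_amp, end_y=0.0,
    )
    trial = TrialRecord(
        trial_id=0, subject_id=0, block_fp=400.0, su_level=1,
        cued_box_indices=frozenset({0}), ws_offset_time=300.0,
        go_onset_time=700.0, target_box_index=0, truth=(g,),
    )
    trace = synthesize_trace(trial, cfg, np.random.default_rng(11))
    events = detect_saccades(trace)
    assert len(events) == 1
    ev = events[0]
    assert abs(ev.amplitude - geom_amp) < 0.5
    truth_onset = trial.ws_offset_time + g.latency_from_fp_onset
    assert abs(ev.onset_time - truth_onset) < 10.0


def test_small_excursion_rejected_by_amplitude():
    # 0.5 deg microsaccade-like excursion with peak speed ~40 deg/s
    tr = _raised_cosine_trace(0.5, dur_ms=math.pi / 2 * 0.5 / 40.0 * 1000.0)
    assert detect_saccades(tr) == []


def test_translation_invariance():
    tr = _raised_cosine_trace(8.0, 50.0)
    shifted = GazeTrace(times=tr.times, x=tr.x + 3.0, y=tr.y - 2.0,
                        valid=tr.valid)
    e0 = detect_saccades(tr)
    e1 = detect_saccades(shifted)
    assert len(e0) == len(e1) == 1
    a, b = e0[0], e1[0]
    assert a.onset_time == b.onset_time and a.offset_time == b.offset_time
    assert a.amplitude == pytest.approx(b.amplitude, abs=1e-9)
    assert b.start_x == pytest.approx(a.start_x + 3.0, abs=1e-9)
    assert b.end_y == pytest.approx(a.end_y - 2.0, abs=1e-9)


@pytest.mark.parametrize("vmin_pair", [(22.0, 40.0), (22.0, 100.0)])
def test_raising_velocity_threshold_never_adds_events(vmin_pair):
    tr = _raised_cosine_trace(6.0, 45.0, noise=0.1, seed=5)
    lo, hi = vmin_pair
    n_lo = len(detect_saccades(tr, DetectionCriteria(min_velocity=lo)))
    n_hi = len(detect_saccades(tr, DetectionCriteria(min_velocity=hi)))
    assert n_hi <= n_lo


def test_events_sorted_disjoint_and_valid(default_config):
    cfg = replace(default_config, noise_sd=0.15)
    trials = generate_experiment(
        replace(cfg, n_subjects=2, trials_per_block=8), 3
    )
    for trial in trials[:20]:
        trace = synthesize_trace(trial, cfg, trace_rng(3, trial.trial_id))
        events = detect_saccades(trace)
        for a, b in zip(events, events[1:]):
            assert a.onset_time < b.onset_time
            assert a.offset_time < b.onset_time  # disjoint
        for e in events:
            inside = (trace.times >= e.onset_time) & (trace.times <= e.offset_time)
            assert trace.valid[inside].all()


# --- artifact rejection ----------------------------------------------------


def _fixation_trial(n=1000, fp=400.0):
    return TrialRecord(
        trial_id=1, subject_id=0, block_fp=fp, su_level=1,
        cued_box_indices=frozenset({0}), ws_offset_time=300.0,
        go_onset_time=300.0 + fp, target_box_index=0, truth=(),
    )


def test_clean_trial_not_rejected():
    tr = _trace(np.zeros(1000), np.zeros(1000))
    rep = reject_artifact_trials([(_fixation_trial(), tr)])[0]
    assert not rep.rejected and rep.reasons == ()


def test_long_blink_rejected():
    valid = np.ones(2000, dtype=bool)
    valid[500:800] = False  # 600 ms gap at 500 Hz
    x = np.zeros(2000)
    x[~valid] = np.nan
    tr = _trace(x, x.copy(), valid=valid)
    rep = reject_artifact_trials([(_fixation_trial(n=2000), tr)])[0]
    assert rep.rejected and "long_blink" in rep.reasons


def test_drift_rejected():
    tr = _trace(np.full(1000, 4.0), np.zeros(1000))
    rep = reject_artifact_trials([(_fixation_trial(), tr)])[0]
    assert rep.rejected and "drift" in rep.reasons


def test_discontinuity_rejected():
    x = np.zeros(1000)
    x[500:] = 8.0  # instantaneous 8 deg step between adjacent samples
    tr = _trace(x, np.zeros(1000))
    rep = reject_artifact_trials([(_fixation_trial(), tr)])[0]
    assert rep.rejected and "discontinuity" in rep.reasons


def test_blink_rejection_rate_matches_rule_analysis(default_config):
    """Monte-Carlo rejection rate vs the analytic expectation of the rules.

    With per-trial blink probability 0.15 and gap lengths U(100, 600) ms, a
    trial is rejected when its gap exceeds 500 ms or exceeds 20% of the
    trace duration; the expected rejected fraction follows from those two
    thresholds per FP level.
    """
    cfg = replace(default_config, blink_probability=0.15,
                  blink_gap_range=(100.0, 600.0), n_subjects=4)
    trials = generate_experiment(cfg, 5)
    pairs = [
        (t, synthesize_trace(t, cfg, trace_rng(5, t.trial_id)))
        for t in trials
    ]
    reports = reject_artifact_trials(pairs)
    frac = np.mean([r.rejected for r in reports])
    lo, hi = cfg.blink_gap_range
    expected = 0.0
    for fp in cfg.fp_levels:
        total = cfg.pre_ws_ms + fp + cfg.trace_tail_ms
        cut = min(500.0, 0.2 * total)
        p_reject = (hi - max(cut, lo)) / (hi - lo)
        expected += 0.15 * p_reject / len(cfg.fp_levels)
    assert abs(frac - expected) < 0.05
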