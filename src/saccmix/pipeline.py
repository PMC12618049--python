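"""End-to-end analysis runs: simulate -> (detect) -> classify -> decompose
-> summarize.

Two routes share the downstream stages.  The *event-level* route classifies
the generator's ground-truth saccades directly — the fast path for
statistical work on the latency structure.  The *trace-level* route renders
raw gaze traces, applies artifact rejection and the velocity/acceleration/
amplitude detector, and classifies the detected events — the full pipeline
a user would run on recorded data.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import (
    CATEGORY_EARLY,
    BoxGeometry,
    boundary_rule_audit,
    classified_frame,
    classify_events,
)
from .detection import (
    ArtifactRules,
    DetectionCriteria,
    detect_saccades,
    reject_artifact_trials,
)
from .inference import (
    mode_counts_by_subject,
    rate_trend,
    sd_vs_fp_trend,
    shannon_surprise,
    spearman_rank_correlation,
    summarize_modes,
    surprise_table,
    two_stage_slope,
)
from .mixture import RULE_LOWEST_LL, decompose_by_block, mixture_report_frame
from .simulate import (
    SimulationConfig,
    TrialRecord,
    generate_experiment,
    synthesize_trace,
    trace_rng,
    truth_to_events,
)


def classify_experiment(
    trials: Sequence[TrialRecord],
    events_by_trial: Optional[dict] = None,
    geometry: Optional[BoxGeometry] = None,
    threshold_ms: Optional[float] = None,
) -> pd.DataFrame:
    """Classify every trial's saccades into one tidy table.

    Without ``events_by_trial`` the ground-truth events are used
    (event-level route).  The returned frame carries ``n_trials`` in its
    attrs so audit fractions use the full trial count as denominator.
    """
    geometry = geometry or BoxGeometry.default()
    frames = []
    for trial in trials:
        events = (events_by_trial.get(trial.trial_id, [])
                  if events_by_trial is not None else truth_to_events(trial))
        classified = classify_events(trial, events, geometry, threshold_ms)
        if classified:
            frames.append(classified_frame(trial, classified))
    if not frames:
        df = pd.DataFrame()
    else:
        df = pd.concat(frames, ignore_index=True)
    df.attrs["n_trials"] = len(trials)
    return df


def apply_block_thresholds(df: pd.DataFrame, decomps: dict) -> pd.DataFrame:
    """Attach per-block mode labels to the early rows of a classified table."""
    df = df.copy()
    early = df["category"] == CATEGORY_EARLY
    for fp, d in decomps.items():
        sel = early & (df["fp"] == fp)
        df.loc[sel, "mode"] = np.where(
            df.loc[sel, "latency"] < d.crossing.threshold, "first", "second"
        )
    return df


def detect_experiment(
    trials: Sequence[TrialRecord],
    config: SimulationConfig,
    seed: int,
    criteria: Optional[DetectionCriteria] = None,
    artifact_rules: Optional[ArtifactRules] = None,
):
    """Render traces, reject artifact trials, detect saccades.

    Returns ``(events_by_trial, artifact_reports, kept_trials)``.  Traces
    are rendered on the fly from per-trial seeded streams so the run is
    deterministic and nothing large is held in memory.
    """
    criteria = criteria or DetectionCriteria()
    events_by_trial: dict[int, list] = {}
    reports = []
    kept = []
    for trial in trials:
        trace = synthesize_trace(trial, config, trace_rng(seed, trial.trial_id))
        report = reject_artifact_trials([(trial, trace)], artifact_rules)[0]
        reports.append(report)
        if report.rejected:
            continue
        kept.append(trial)
        events_by_trial[trial.trial_id] = detect_saccades(trace, criteria)
    return events_by_trial, reports, kept


def run_analysis(
    config: SimulationConfig,
    seed: int,
    use_traces: bool = False,
    criteria: Optional[DetectionCriteria] = None,
    k_range=range(2, 6),
    rule: str = RULE_LOWEST_LL,
    geometry: Optional[BoxGeometry] = None,
) -> dict:
    """Full analysis; returns a JSON-serializable report dict.

    Report contents: the surprise table, classification audit, per-block
    mixture fits and crossing thresholds, mode summary cells, latency/SD/
    rate trends, and the between-subject mode-count correlation.
    """
    geometry = geometry or BoxGeometry.default()
    trials = generate_experiment(config, seed, geometry)
    if use_traces:
        events_by_trial, artifact_reports, kept = detect_experiment(
            trials, config, seed, criteria
        )
        df = classify_experiment(kept, events_by_trial, geometry)
        df.attrs["n_trials"] = len(kept)
        n_rejected = sum(r.rejected for r in artifact_reports)
    else:
        df = classify_experiment(trials, geometry=geometry)
        n_rejected = 0
    audit = boundary_rule_audit(df)
    early = df[df["category"] == CATEGORY_EARLY]
    lat_by_block = {
        float(fp): g["latency"].to_numpy()
        for fp, g in early.groupby("fp")
    }
    decomps = decompose_by_block(lat_by_block, k_range=k_range, rule=rule,
                                 seed=seed)
    df = apply_block_thresholds(df, decomps)
    early = df[df["category"] == CATEGORY_EARLY]

    summaries = summarize_modes(early)
    mode2 = early[early["mode"] == "second"]
    mode1 = early[early["mode"] == "first"]
    slope_mode2 = two_stage_slope(mode2, "latency", "fp")
    slope_mode1 = two_stage_slope(mode1, "latency", "fp")
    sd_trends = sd_vs_fp_trend(early)
    counts = mode_counts_by_subject(early)
    rates = rate_trend(counts)
    per_subject = counts.pivot_table(index="subject", columns="mode",
                                     values="count", aggfunc="sum")
    count_corr = spearman_rank_correlation(
        per_subject["first"].to_numpy(), per_subject["second"].to_numpy()
    )
    sup = surprise_table(config.su_probabilities)
    report = {
        "seed": int(seed),
        "n_trials": int(len(trials)),
        "n_artifact_rejected": int(n_rejected),
        "surprise_bits": {
            str(s.su_level): round(s.surprise, 6) for s in sup
        },
        "audit": audit,
        "blocks": {
            str(int(fp)): {
                "selected_k": d.selected.k,
                "threshold_ms": round(d.crossing.threshold, 1),
                "means_ms": [round(m, 1) for m in d.selected.means],
                "sds_ms": [round(s, 1) for s in d.selected.sds],
                "weights": [round(w, 4) for w in d.selected.weights],
                "loglik": round(d.selected.loglik, 2),
                "n_obs": d.selected.n_obs,
            }
            for fp, d in decomps.items()
        },
        "slopes": {
            "mode2_latency_vs_fp": {
                "slope": slope_mode2.group_mean_slope,
                "se": slope_mode2.group_se,
            },
            "mode1_latency_vs_fp": {
                "slope": slope_mode1.group_mean_slope,
                "se": slope_mode1.group_se,
            },
            "mode2_sd_vs_fp": {
                "slope": sd_trends["second"].slope,
                "se": sd_trends["second"].se,
            },
            "mode1_sd_vs_fp": {
                "slope": sd_trends["first"].slope,
                "se": sd_trends["first"].se,
            },
            "mode1_log_rate_vs_fp": {
                "slope": rates["first"].slope,
                "se": rates["first"].se,
            },
            "mode2_log_rate_vs_fp": {
                "slope": rates["second"].slope,
                "se": rates["second"].se,
            },
        },
        "kinematics": {
            "vmax_mode2_minus_mode1": float(
                mode2["vmax"].mean() - mode1["vmax"].mean()
            ),
            "amplitude_mode2_minus_mode1": float(
                mode2["amplitude"].mean() - mode1["amplitude"].mean()
            ),
        },
        "mode_count_spearman": count_corr,
        "mode_counts": {
            "first": int(len(mode1)),
            "second": int(len(mode2)),
        },
    }
    report["_frames"] = {
        "classified": df,
        "summaries": summaries,
        "mixture_report": mixture_report_frame(decomps),
    }
    return report


def report_without_frames(report: dict) -> dict:
    return {k: v for k, v in report.items() if not k.startswith("_")}
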