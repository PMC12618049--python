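"""Closed-form statistics, rank correlation, and trend estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from saccmix import (
    fit_random_intercept,
    rate_trend,
    sd_vs_fp_trend,
    shannon_surprise,
    spearman_rank_correlation,
    summarize_modes,
    surprise_table,
    two_stage_slope,
)


# --- Shannon surprise ------------------------------------------------------


@pytest.mark.parametrize("p,bits", [
    (1.0, 0.0), (0.5, 1.0), (1 / 3, 1.58), (0.25, 2.0),
])
def test_surprise_values(p, bits):
    assert shannon_surprise(p) == pytest.approx(bits, abs=0.005)


def test_surprise_table_levels():
    table = surprise_table([1.0, 0.5, 1 / 3, 0.25])
    assert [(s.su_level, round(s.surprise, 2)) for s in table] == [
        (1, 0.0), (2, 1.0), (3, 1.58), (4, 2.0)
    ]


@pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
def test_surprise_rejects_invalid_probability(p):
    with pytest.raises(ValueError):
        shannon_surprise(p)


@settings(derandomize=True, deadline=None)
@given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
def test_surprise_log_additivity(p, q):
    assert shannon_surprise(p * q) == pytest.approx(
        shannon_surprise(p) + shannon_surprise(q), abs=1e-9
    )


# --- Spearman --------------------------------------------------------------


def test_spearman_perfect_monotone():
    assert spearman_rank_correlation([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
    assert spearman_rank_correlation([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)


def test_spearman_zero_variance_raises():
    with pytest.raises(ValueError):
        spearman_rank_correlation([1, 1, 1], [1, 2, 3])


def _midrank(values):
    """Brute-force midranks: average position of equal values, 1-based."""
    values = list(values)
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2.0)
    return np.array(out)


def test_spearman_matches_brute_force_midrank_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(5, 40))
        x = rng.integers(0, 5, n).astype(float)  # tie-rich
        y = rng.integers(0, 5, n).astype(float)
        rx, ry = _midrank(x), _midrank(y)
        if rx.std() == 0 or ry.std() == 0:
            continue
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert spearman_rank_correlation(x, y) == pytest.approx(oracle, abs=1e-12)


def test_spearman_agrees_with_scipy(rng):
    from scipy.stats import spearmanr

    x = rng.integers(0, 8, 60).astype(float)
    y = x + rng.integers(0, 8, 60)
    assert spearman_rank_correlation(x, y) == pytest.approx(
        spearmanr(x, y).statistic, abs=1e-12)


@settings(derandomize=True, deadline=None)
@given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=30, unique=True))
def test_spearman_invariant_under_monotone_transform(xs):
    rng = np.random.default_rng(0)
    ys = rng.normal(size=len(xs))
    base = spearman_rank_correlation(np.asarray(xs, float), ys)
    transformed = spearman_rank_correlation(np.exp(np.asarray(xs) / 100.0), ys)
    assert transformed == pytest.approx(base, abs=1e-12)


# --- two-stage slope -------------------------------------------------------


def _linear_table(beta=0.5, intercepts=(3, 3, 3, 3, 3), noise=0.0, rng=None):
    rows = []
    for s, b0 in enumerate(intercepts):
        for x in (400, 900, 1400, 1900):
            eps = rng.normal(0, noise) if noise else 0.0
            rows.append({"subject": s, "fp": x, "y": b0 + beta * x + eps})
    return pd.DataFrame(rows)


def test_two_stage_exact_on_noiseless_data():
    est = two_stage_slope(_linear_table(), "y", "fp")
    assert est.group_mean_slope == pytest.approx(0.5, abs=1e-12)
    assert est.group_se == pytest.approx(0.0, abs=1e-12)
    assert est.n_subjects == 5
    assert est.group_mean_slope == pytest.approx(
        np.mean(est.per_subject_slopes))


def test_two_stage_drops_single_level_subjects(caplog):
    df = _linear_table()
    df = pd.concat([df, pd.DataFrame([{"subject": 99, "fp": 400, "y": 1.0}])],
                   ignore_index=True)
    est = two_stage_slope(df, "y", "fp")
    assert est.n_subjects == 5


def test_two_stage_recovers_slope_with_subject_intercepts():
    """Calibration: ~95% of replicates cover the generating slope at 2 SE."""
    rng = np.random.default_rng(42)
    beta = 0.61
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        intercepts = rng.normal(200, 40, 8)
        df = _linear_table(beta=beta, intercepts=intercepts, noise=30.0,
                           rng=rng)
        est = two_stage_slope(df, "y", "fp")
        if abs(est.group_mean_slope - beta) <= 2 * est.group_se:
            hits += 1
    assert hits / n_rep >= 0.90


# --- SD trend --------------------------------------------------------------


def test_sd_trend_null_when_sigma_constant(rng):
    rows = []
    for fp in (400, 900, 1400, 1900):
        for v in rng.normal(500, 80, 400):
            rows.append({"fp": fp, "latency": v, "mode": "second"})
    trend = sd_vs_fp_trend(pd.DataFrame(rows))["second"]
    assert abs(trend.slope) <= 2 * trend.se


def test_sd_trend_recovers_generating_slope(rng):
    rows = []
    for fp in (400, 900, 1400, 1900):
        sigma = 1.0 + 0.17 * fp
        for v in rng.normal(200 + 0.61 * fp, sigma, 500):
            rows.append({"fp": fp, "latency": v, "mode": "second"})
    trend = sd_vs_fp_trend(pd.DataFrame(rows))["second"]
    assert trend.slope == pytest.approx(0.17, abs=2 * trend.se)


def test_sd_trend_on_default_experiment_truth_labels(default_experiment):
    """With ground-truth process labels, the impulsive SD is flat in FP and
    the anticipatory SD grows at the generating 0.17 ms/ms."""
    from saccmix.simulate import truth_frame

    tf = truth_frame(default_experiment)
    tf = tf[tf["process"] != "visually_guided"].rename(
        columns={"latency_ms": "latency"})
    tf["mode"] = tf["process"].map(
        {"impulsive": "first", "anticipatory": "second"})
    trends = sd_vs_fp_trend(tf)
    assert abs(trends["first"].slope) <= 2 * trends["first"].se
    assert trends["second"].slope == pytest.approx(
        0.17, abs=2 * trends["second"].se)


def test_sd_trend_underpopulated_raises():
    df = pd.DataFrame({"fp": [400] * 5, "latency": range(5),
                       "mode": ["first"] * 5})
    with pytest.raises(ValueError):
        sd_vs_fp_trend(df)


# --- rate trend ------------------------------------------------------------


def test_rate_trend_exact_on_noiseless_loglinear_counts():
    rows = []
    for s in range(3):
        for fp in (400, 900, 1400, 1900):
            rows.append({"subject": s, "fp": fp, "mode": "first",
                         "count": 100.0 * np.exp(-0.001 * fp)})
    trend = rate_trend(pd.DataFrame(rows))["first"]
    assert trend.slope == pytest.approx(-0.001, abs=1e-6)


def test_rate_trend_all_zero_raises():
    df = pd.DataFrame({"subject": [0, 0], "fp": [400, 900],
                       "mode": ["first", "first"], "count": [0, 0]})
    with pytest.raises(ValueError, match="zero"):
        rate_trend(df)


def test_rate_trend_negative_counts_raise():
    df = pd.DataFrame({"subject": [0], "fp": [400], "mode": ["first"],
                       "count": [-1]})
    with pytest.raises(ValueError):
        rate_trend(df)


# --- random-intercept contract --------------------------------------------


def test_random_intercept_exact_on_balanced_noiseless_data():
    df = _linear_table(beta=0.25, intercepts=(1, 2, 3, 4, 5))
    fit = fit_random_intercept(df, "y", ["fp"], family="gaussian")
    assert fit.coefficients["fp"] == pytest.approx(0.25, abs=1e-6)
    assert fit.converged


def test_random_intercept_bic_identity(rng):
    df = _linear_table(beta=0.3, intercepts=rng.normal(5, 2, 6),
                       noise=10.0, rng=rng)
    fit = fit_random_intercept(df, "y", ["fp"], family="gaussian")
    p = 2 + 2  # const + slope + RE variance + residual variance
    assert fit.bic == pytest.approx(-2 * fit.loglik + p * np.log(len(df)))


def test_random_intercept_agrees_with_two_stage(rng):
    """Mixed-model fixed effect vs the two-stage estimator on mode-2-like
    data: the two routes agree within combined uncertainty."""
    intercepts = rng.normal(200, 50, 12)
    df = _linear_table(beta=0.61, intercepts=intercepts, noise=80.0, rng=rng)
    two = two_stage_slope(df, "y", "fp")
    mixed = fit_random_intercept(df, "y", ["fp"], family="gaussian")
    combined = np.hypot(two.group_se, mixed.se["fp"])
    assert abs(two.group_mean_slope - mixed.coefficients["fp"]) <= \
        2 * max(combined, 1e-6)


def test_random_intercept_poisson_slope():
    rng = np.random.default_rng(9)
    rows = []
    for s in range(10):
        base = rng.uniform(5, 20)
        for fp in (400, 900, 1400, 1900):
            lam = base * np.exp(-0.001 * fp)
            rows.append({"subject": s, "fp": fp,
                         "count": rng.poisson(lam * 20)})
    df = pd.DataFrame(rows)
    fit = fit_random_intercept(df, "count", ["fp"], family="poisson")
    assert fit.coefficients["fp"] == pytest.approx(-0.001,
                                                   abs=3 * fit.se["fp"])


# --- summaries -------------------------------------------------------------


def test_summarize_modes_empty():
    assert len(summarize_modes(pd.DataFrame())) == 0


def test_summarize_modes_exact_cells():
    df = pd.DataFrame({
        "mode": ["first", "first", "second"],
        "fp": [400, 400, 400],
        "su": [1, 1, 1],
        "latency": [100.0, 200.0, 600.0],
        "vmax": [300.0, 310.0, 330.0],
        "amplitude": [10.0, 12.0, 13.0],
    })
    out = summarize_modes(df)
    first = out[out["mode"] == "first"].iloc[0]
    assert first["n"] == 2
    assert first["latency_mean"] == 150.0
    assert first["latency_sd"] == pytest.approx(np.std([100, 200], ddof=1))
    second = out[out["mode"] == "second"].iloc[0]
    assert second["n"] == 1 and np.isnan(second["latency_sd"])
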