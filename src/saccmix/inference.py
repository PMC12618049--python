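"""Summary statistics and trend estimators for classified early saccades.

Covers the closed-form spatial-uncertainty measure (Shannon surprise,
``-log2 p`` bits), mode x FP x SU summary tables, tie-corrected Spearman
rank correlation, and the trend estimators that recover the generator's
structure: a two-stage per-subject-slope estimator (OLS slope per subject,
then group mean and SE), a block-SD-versus-FP trend (scalar expectancy), a
Poisson log-linear occurrence-rate trend, and a contract-level
random-intercept model fit with BIC, delegated to statsmodels.

The two-stage estimator is the package's transparent stand-in for the fixed
effect of a subject-random-intercept mixed model: with balanced designs the
group mean of per-subject OLS slopes estimates the same quantity, and tests
require the two routes to agree within their combined uncertainty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Reporting-only significance convention carried alongside estimates.
ALPHA = 0.01


@dataclass(frozen=True)
class SurpriseLevel:
    su_level: int
    probability: float
    surprise: float  # bits


@dataclass(frozen=True)
class SlopeEstimate:
    response: str
    predictor: str
    per_subject_slopes: tuple[float, ...]
    group_mean_slope: float
    group_se: float
    n_subjects: int


@dataclass(frozen=True)
class TrendEstimate:
    """A pooled (non-subject-wise) slope with its standard error."""

    response: str
    predictor: str
    slope: float
    se: float
    n_points: int


@dataclass(frozen=True)
class RandomInterceptFit:
    family: str
    coefficients: dict
    se: dict
    loglik: float
    bic: float
    n_obs: int
    converged: bool


def shannon_surprise(p):
    """Shannon surprise ``-log2 p`` in bits; exact for dyadic probabilities."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("probability must lie in (0, 1]")
    out = -np.log2(arr) + 0.0  # normalize -0.0 at p = 1
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def surprise_table(probabilities: Sequence[float]) -> list[SurpriseLevel]:
    """One SurpriseLevel per SU condition, levels numbered from 1."""
    return [
        SurpriseLevel(su_level=i + 1, probability=float(p),
                      surprise=shannon_surprise(p))
        for i, p in enumerate(probabilities)
    ]


def summarize_modes(
    classified: pd.DataFrame,
    group_keys: Sequence[str] = ("mode", "fp", "su"),
) -> pd.DataFrame:
    """Exact per-cell n, means and SDs (ddof=1; SD blank when n < 2)."""
    if len(classified) == 0:
        return pd.DataFrame(
            columns=[*group_keys, "n", "latency_mean", "latency_sd",
                     "vmax_mean", "amplitude_mean"]
        )
    grouped = classified.groupby(list(group_keys), dropna=False)
    out = grouped.agg(
        n=("latency", "size"),
        latency_mean=("latency", "mean"),
        latency_sd=("latency", lambda v: v.std(ddof=1) if len(v) >= 2 else np.nan),
        vmax_mean=("vmax", "mean"),
        amplitude_mean=("amplitude", "mean"),
    ).reset_index()
    return out.sort_values(list(group_keys)).reset_index(drop=True)


def spearman_rank_correlation(x, y) -> float:
    """Pearson correlation of midranked data (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero-variance ranks: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def two_stage_slope(
    table: pd.DataFrame, response: str, predictor: str,
    subject: str = "subject",
) -> SlopeEstimate:
    """Per-subject OLS slope, then group mean and SE across subjects.

    Subjects with a single predictor level cannot contribute a slope and
    are dropped with a logged warning.
    """
    slopes = []
    dropped = []
    for sid, g in table.groupby(subject):
        if g[predictor].nunique() < 2:
            dropped.append(sid)
            continue
        slope = np.polyfit(g[predictor].to_numpy(dtype=float),
                           g[response].to_numpy(dtype=float), 1)[0]
        slopes.append(float(slope))
    if dropped:
        logger.warning(
            "two_stage_slope: dropped %d subject(s) with a single %s level: %s",
            len(dropped), predictor, dropped,
        )
    if not slopes:
        raise ValueError("no subject contributed two predictor levels")
    arr = np.asarray(slopes)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return SlopeEstimate(
        response=response, predictor=predictor,
        per_subject_slopes=tuple(slopes),
        group_mean_slope=float(arr.mean()), group_se=se,
        n_subjects=arr.size,
    )


def sd_vs_fp_trend(
    early: pd.DataFrame, latency: str = "latency", fp: str = "fp",
    mode: str = "mode", min_per_block: int = 10,
) -> dict:
    """Per-mode slope of pooled block-level latency SD on FP.

    The point estimate is simple least squares on the block SDs (subjects
    pooled within block).  Its SE propagates the sampling variance of each
    SD estimate, var(SD_b) ~= SD_b^2 / (2 (n_b - 1)), through the OLS
    weights; with only four collinear block SDs a residual-based SE would
    be numerically meaningless.
    """
    out = {}
    for m, g in early.groupby(mode, dropna=True):
        cells = g.groupby(fp)[latency].agg(["std", "size"])
        cells = cells[cells["size"] >= min_per_block]
        if len(cells) < 2:
            raise ValueError(
                f"mode {m!r}: need >= 2 FP blocks with >= {min_per_block} "
                "saccades each"
            )
        xs = cells.index.to_numpy(dtype=float)
        sds = cells["std"].to_numpy(dtype=float)
        ns = cells["size"].to_numpy(dtype=float)
        xdev = xs - xs.mean()
        coef = xdev / (xdev**2).sum()
        slope = float(coef @ sds)
        var_sd = sds**2 / (2.0 * (ns - 1.0))
        se = float(np.sqrt((coef**2 * var_sd).sum()))
        out[m] = TrendEstimate(
            response=f"sd({latency})", predictor=fp, slope=slope, se=se,
            n_points=len(cells),
        )
    return out


def rate_trend(
    counts: pd.DataFrame, count: str = "count", fp: str = "fp",
    mode: str = "mode", subject: str = "subject",
) -> dict:
    """Per-mode Poisson log-linear slope of occurrence counts on FP.

    Fits ``count ~ Poisson(exp(b0 + b1 FP + offset_s))`` per mode, with the
    per-subject offset ``log(mean count across blocks)`` absorbing subject
    level differences; delegated to statsmodels GLM (IRLS).  Subjects with
    all-zero counts for a mode carry no rate information and are dropped;
    a mode with no counts at all raises.
    """
    import statsmodels.api as sm

    if (counts[count] < 0).any():
        raise ValueError("counts must be non-negative")
    out = {}
    for m, g in counts.groupby(mode, dropna=True):
        subj_mean = g.groupby(subject)[count].transform("mean")
        keep = subj_mean > 0
        g = g[keep]
        if len(g) == 0 or g[count].sum() == 0:
            raise ValueError(f"mode {m!r}: all counts are zero")
        offset = np.log(subj_mean[keep].to_numpy(dtype=float))
        exog = sm.add_constant(g[fp].to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-integer counts are fine
            res = sm.GLM(
                g[count].to_numpy(dtype=float), exog,
                family=sm.families.Poisson(), offset=offset,
            ).fit()
        out[m] = TrendEstimate(
            response=f"log-rate({count})", predictor=fp,
            slope=float(res.params[1]), se=float(res.bse[1]),
            n_points=len(g),
        )
    return out


def fit_random_intercept(
    table: pd.DataFrame, response: str, predictors: Sequence[str],
    subject: str = "subject", family: str = "gaussian",
) -> RandomInterceptFit:
    """Subject-random-intercept model fit (contract-level, delegated).

    Gaussian: statsmodels MixedLM with a random intercept per subject,
    maximum likelihood, BIC = -2 LL + p log(n) with p counting the fixed
    effects plus the two variance parameters.  Poisson: statsmodels GLM
    with a log link and per-subject log-mean offsets — a multiplicative
    subject-level normalization standing in for the random intercept (the
    count analyses here need only the FP slope); p counts the fixed
    effects.  Non-convergence raises with diagnostics.
    """
    import statsmodels.api as sm

    y = table[response].to_numpy(dtype=float)
    X = sm.add_constant(table[list(predictors)].to_numpy(dtype=float))
    names = ["const", *predictors]
    n = len(table)
    if family == "gaussian":
        model = sm.MixedLM(y, X, groups=table[subject].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False)
        if not res.converged:
            raise RuntimeError(
                f"MixedLM did not converge: {res.summary()}"
            )
        p = len(names) + 2  # fixed effects + RE variance + residual variance
        ll = float(res.llf)
        return RandomInterceptFit(
            family="gaussian",
            coefficients={k: float(v) for k, v in zip(names, res.fe_params)},
            se={k: float(v) for k, v in zip(names, res.bse_fe)},
            loglik=ll, bic=-2.0 * ll + p * np.log(n), n_obs=n, converged=True,
        )
    if family == "poisson":
        subj_mean = table.groupby(subject)[response].transform("mean")
        keep = (subj_mean > 0).to_numpy()
        offset = np.log(subj_mean.to_numpy(dtype=float)[keep])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                y[keep], X[keep], family=sm.families.Poisson(), offset=offset,
            ).fit()
        if not res.converged:
            raise RuntimeError(f"Poisson GLM did not converge: {res.summary()}")
        p = len(names)
        ll = float(res.llf)
        return RandomInterceptFit(
            family="poisson",
            coefficients={k: float(v) for k, v in zip(names, res.params)},
            se={k: float(v) for k, v in zip(names, res.bse)},
            loglik=ll, bic=-2.0 * ll + p * np.log(int(keep.sum())),
            n_obs=int(keep.sum()), converged=True,
        )
    raise ValueError(f"unknown family: {family!r}")


def mode_counts_by_subject(
    early: pd.DataFrame, subject: str = "subject", mode: str = "mode",
    fp: str = "fp", subjects: Optional[Sequence] = None,
    fps: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Complete subject x FP x mode count grid (zeros included)."""
    modes = sorted(early[mode].dropna().unique())
    subjects = sorted(early[subject].unique()) if subjects is None else list(subjects)
    fps = sorted(early[fp].unique()) if fps is None else list(fps)
    grid = pd.MultiIndex.from_product(
        [subjects, fps, modes], names=[subject, fp, mode]
    )
    counts = (
        early.dropna(subset=[mode])
        .groupby([subject, fp, mode]).size()
        .reindex(grid, fill_value=0)
        .rename("count").reset_index()
    )
    return counts
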