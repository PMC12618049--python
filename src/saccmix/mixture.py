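"""Univariate Gaussian-mixture EM for early-saccade latency distributions.

Early-saccade latencies in blocked foreperiod tasks are bimodal: a
short-latency impulsive component with an FP-independent mean and a
long-latency anticipatory component whose mean and spread scale with the
foreperiod.  This module fits k-component Gaussian mixtures by
expectation-maximization (written here, not delegated), selects k across a
range, and computes the analytic crossing point of the two components —
the latency at which the weighted component densities are equal — which
serves as the first/second-mode classification threshold.

Two selection rules are provided.  ``lowest_ll`` picks the fit with
the minimal log-likelihood, the literal reading of a selection-by-"lowest
LL" convention sometimes seen in the applied literature; since the
log-likelihood is non-decreasing in k, this effectively selects the
smallest k and is statistically unconventional, so a warning is logged.
``bic`` picks the minimal Bayesian information criterion
``-2 LL + (3k - 1) log n``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .classification import assign_mode

logger = logging.getLogger(__name__)

RULE_LOWEST_LL = "lowest_ll"
RULE_BIC = "bic"

SD_FLOOR_MS = 1.0  # prevents variance collapse onto a single point


class DegenerateFitWarning(UserWarning):
    """A component collapsed (weight below 1/n or SD at the floor)."""


@dataclass(frozen=True)
class MixtureFit:
    k: int
    weights: tuple[float, ...]   # simplex, ordered with means
    means: tuple[float, ...]     # ms, ascending
    sds: tuple[float, ...]       # ms, >= SD floor
    loglik: float                # nats, observed-data log-likelihood
    n_iter: int
    converged: bool
    n_obs: int
    degenerate: bool = False
    loglik_history: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(self.means[i] > self.means[i + 1] for i in range(self.k - 1)):
            raise ValueError("means must be ascending")

    def bic(self) -> float:
        p = 3 * self.k - 1
        return -2.0 * self.loglik + p * math.log(self.n_obs)

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * norm.pdf(x, m, s)
        return out


@dataclass(frozen=True)
class CrossingPoint:
    threshold: float           # ms; NaN when no crossing exists
    bracket: tuple[float, float]
    exists: bool

    def __post_init__(self) -> None:
        if self.exists and not (self.bracket[0] < self.threshold < self.bracket[1]):
            raise ValueError("threshold must lie strictly inside the bracket")


def mixture_loglik(x: np.ndarray, weights, means, sds) -> float:
    """Observed-data log-likelihood sum_i log sum_j w_j N(x_i; mu_j, sd_j)."""
    log_comp = (
        np.log(np.asarray(weights))[None, :]
        + norm.logpdf(np.asarray(x)[:, None],
                      np.asarray(means)[None, :],
                      np.asarray(sds)[None, :])
    )
    return float(logsumexp(log_comp, axis=1).sum())


def _em_once(
    x: np.ndarray, weights: np.ndarray, means: np.ndarray, sds: np.ndarray,
    max_iter: int, tol: float, sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = x.size
    prev_ll = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = (
            np.log(weights)[None, :]
            + norm.logpdf(x[:, None], means[None, :], sds[None, :])
        )
        log_norm = logsumexp(log_comp, axis=1, keepdims=True)
        ll = float(log_norm.sum())
        history.append(ll)
        if ll - prev_ll < tol and it > 1:
            converged = True
            break
        prev_ll = ll
        resp = np.exp(log_comp - log_norm)
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
    return weights, means, sds, history[-1], it, converged, history


def em_fit(
    latencies: Sequence[float], k: int, max_iter: int = 1000,
    tol: float = 1e-8, n_restarts: int = 10, seed: int = 0,
    sd_floor: float = SD_FLOOR_MS,
) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    Initialization: component means at k evenly spaced sample quantiles,
    pooled SD, uniform weights; restart 0 is this deterministic start and
    the remaining ``n_restarts - 1`` jitter the means with a fixed-seed
    stream.  The best restart by final log-likelihood wins; components are
    relabeled so means ascend.  Input order does not matter (the sample is
    sorted on entry).  Degenerate outcomes — a component weight below
    ``1/n`` or an SD pinned at the floor — are flagged on the returned fit
    and warned about, never silently dropped.
    """
    x = np.sort(np.asarray(latencies, dtype=float))
    if x.size == 0 or not np.isfinite(x).all():
        raise ValueError("latencies must be non-empty and finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = x.size
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} observations for k={k}; got {n}")
    sample_sd = float(x.std())
    if k == 1:
        mu = float(x.mean())
        sd = max(sample_sd, sd_floor)
        ll = mixture_loglik(x, [1.0], [mu], [sd])
        degenerate = sample_sd < sd_floor
        fit = MixtureFit(
            k=1, weights=(1.0,), means=(mu,), sds=(sd,), loglik=ll,
            n_iter=0, converged=True, n_obs=n, degenerate=degenerate,
            loglik_history=(ll,),
        )
        if degenerate:
            warnings.warn("zero-variance sample: SD pinned at floor",
                          DegenerateFitWarning)
        return fit
    if sample_sd == 0.0:
        raise ValueError(
            "all latencies identical: a multi-component fit is degenerate"
        )
    base_means = np.quantile(x, (np.arange(k) + 1.0) / (k + 1.0))
    sd0 = max(sample_sd, sd_floor)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(n_restarts, 1)):
        means0 = base_means.copy()
        if r > 0:
            means0 = means0 + rng.normal(0.0, sd0 / 2.0, size=k)
        weights0 = np.full(k, 1.0 / k)
        sds0 = np.full(k, sd0)
        w, m, s, ll, it, conv, hist = _em_once(
            x, weights0, means0, sds0, max_iter, tol, sd_floor
        )
        if best is None or ll > best[3]:
            best = (w, m, s, ll, it, conv, hist)
    w, m, s, ll, it, conv, hist = best
    order = np.argsort(m)
    w, m, s = w[order], m[order], s[order]
    w = w / w.sum()  # exact simplex after float round-off
    degenerate = bool((w < 1.0 / n).any() or (s <= sd_floor).any())
    if degenerate:
        warnings.warn(
            f"degenerate {k}-component fit (weight < 1/n or SD at floor)",
            DegenerateFitWarning,
        )
    return MixtureFit(
        k=k, weights=tuple(map(float, w)), means=tuple(map(float, m)),
        sds=tuple(map(float, s)), loglik=ll, n_iter=it, converged=conv,
        n_obs=n, degenerate=degenerate, loglik_history=tuple(hist),
    )


def select_mixture(fits: Sequence[MixtureFit],
                   rule: str = RULE_LOWEST_LL) -> MixtureFit:
    """Pick one fit across k; ties break toward the smaller k.

    ``lowest_ll`` returns the fit with the minimal log-likelihood
    (with a logged warning about the statistical oddity of preferring the
    worst-fitting mixture; in practice it selects the smallest k).  ``bic``
    returns the minimal ``-2 LL + (3k - 1) log n``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("fits must share the same data (n_obs differs)")
    ordered = sorted(fits, key=lambda f: f.k)
    if rule == RULE_LOWEST_LL:
        logger.warning(
            "selecting the mixture with the LOWEST log-likelihood; this "
            "prefers the worst-fitting k and is kept only for parity with "
            "the literal selection convention — consider rule='bic'"
        )
        return min(ordered, key=lambda f: f.loglik)
    if rule == RULE_BIC:
        return min(ordered, key=lambda f: f.bic())
    raise ValueError(f"unknown selection rule: {rule!r}")


def crossing_point(
    fit: Optional[MixtureFit] = None, *, weights=None, means=None, sds=None,
) -> CrossingPoint:
    """Latency where the two weighted component densities are equal.

    Solves ``w1 N(x; mu1, s1) = w2 N(x; mu2, s2)``.  Taking logs yields
    ``a x^2 + b x + c = 0`` with

        a = 1/(2 s1^2) - 1/(2 s2^2)
        b = mu2/s2^2 - mu1/s1^2
        c = mu1^2/(2 s1^2) - mu2^2/(2 s2^2) + log(w2 s1) - log(w1 s2)

    (equal SDs reduce it to the linear case).  The root returned is the one
    in the open interval (mu1, mu2) at which dominance flips from the
    low-mean to the high-mean component; ``exists`` is False when no real
    root lies there.
    """
    if fit is not None:
        if fit.k != 2:
            raise ValueError("crossing_point requires a 2-component fit")
        weights, means, sds = fit.weights, fit.means, fit.sds
    (w1, w2), (m1, m2), (s1, s2) = weights, means, sds
    if m1 > m2:
        (w1, w2), (m1, m2), (s1, s2) = (w2, w1), (m2, m1), (s2, s1)
    if m1 == m2:
        raise ValueError("component means must be distinct")
    a = 1.0 / (2.0 * s1**2) - 1.0 / (2.0 * s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = (m1**2 / (2.0 * s1**2) - m2**2 / (2.0 * s2**2)
         + math.log(w2 * s1) - math.log(w1 * s2))
    if a == 0.0:
        roots = [-c / b] if b != 0 else []
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            # numerically stable quadratic roots
            q = -0.5 * (b + math.copysign(sq, b))
            roots = sorted({q / a, c / q if q != 0 else np.nan})
            roots = [r for r in roots if np.isfinite(r)]
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        return CrossingPoint(threshold=float("nan"), bracket=(m1, m2),
                             exists=False)
    if len(inside) > 1:
        # keep the root where the density difference flips from component 1
        # dominant to component 2 dominant (g'(x) < 0 for g = log f1 - log f2)
        def gprime(r):
            return -2.0 * a * r - b
        inside = [r for r in inside if gprime(r) < 0] or inside[:1]
    return CrossingPoint(threshold=float(inside[0]), bracket=(m1, m2),
                         exists=True)


@dataclass(frozen=True)
class BlockDecomposition:
    fp: float
    fits: dict            # k -> MixtureFit
    selected: MixtureFit
    crossing: CrossingPoint
    modes: np.ndarray     # per-observation "first"/"second" labels


def decompose_by_block(
    latencies_by_block: dict,
    k_range: Iterable[int] = range(2, 6),
    rule: str = RULE_LOWEST_LL,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    n_restarts: int = 10,
) -> dict:
    """Fit, select and threshold each FP block's early-latency sample.

    ``latencies_by_block`` maps the block FP (ms) to its pooled early
    latencies.  Each block must hold at least ``5 * max(k_range)``
    observations.  When the selected fit has k > 2 the crossing between the
    two lowest-mean components is used (warned).  Returns a dict
    ``fp -> BlockDecomposition``; the per-observation mode labels follow the
    classification module's threshold rule (first strictly below, second at
    or above).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or min(ks) < 2:
        raise ValueError("k_range must contain integers >= 2")
    out = {}
    for fp in sorted(latencies_by_block):
        lat = np.asarray(latencies_by_block[fp], dtype=float)
        if lat.size < 5 * max(ks):
            raise ValueError(
                f"block FP={fp}: {lat.size} early latencies, need "
                f">= {5 * max(ks)} for k up to {max(ks)}"
            )
        fits = {
            k: em_fit(lat, k, max_iter=max_iter, tol=tol,
                      n_restarts=n_restarts, seed=seed + k)
            for k in ks
        }
        selected = select_mixture(list(fits.values()), rule=rule)
        if selected.k == 2:
            cp = crossing_point(selected)
        else:
            warnings.warn(
                f"block FP={fp}: selected k={selected.k} > 2; using the "
                "crossing of the two lowest-mean components as threshold"
            )
            cp = crossing_point(
                weights=selected.weights[:2], means=selected.means[:2],
                sds=selected.sds[:2],
            )
        if not cp.exists:
            raise RuntimeError(
                f"block FP={fp}: no density crossing between the component "
                "means; cannot define a mode threshold"
            )
        modes = np.array([assign_mode(v, cp.threshold) for v in lat])
        out[fp] = BlockDecomposition(
            fp=float(fp), fits=fits, selected=selected, crossing=cp,
            modes=modes,
        )
    return out


def posterior_cut_discrepancy(fit: MixtureFit, latencies) -> dict:
    """Measure where the density-crossing cut disagrees with the posterior.

    With asymmetric weights the density-equality threshold differs from a
    maximum-posterior assignment only in the region between the two cut
    points; this reports how many observations fall in that region.
    """
    if fit.k != 2:
        raise ValueError("requires a 2-component fit")
    cp = crossing_point(fit)
    x = np.asarray(latencies, dtype=float)
    thr_labels = x >= cp.threshold if cp.exists else np.zeros(x.size, bool)
    log_post = (
        np.log(np.asarray(fit.weights))[None, :]
        + norm.logpdf(x[:, None], np.asarray(fit.means)[None, :],
                      np.asarray(fit.sds)[None, :])
    )
    post_labels = log_post[:, 1] > log_post[:, 0]
    disagree = int((thr_labels != post_labels).sum())
    return {
        "n": int(x.size),
        "n_disagree": disagree,
        "fraction_disagree": disagree / x.size if x.size else 0.0,
        "threshold": cp.threshold if cp.exists else None,
    }


def mixture_report_frame(decomps: dict):
    """Per-block mixture summary table (selected fit + threshold)."""
    import pandas as pd

    rows = []
    for fp, d in sorted(decomps.items()):
        f = d.selected
        rows.append({
            "fp": fp,
            "k": f.k,
            "weights": ";".join(f"{w:.6g}" for w in f.weights),
            "means_ms": ";".join(f"{m:.6g}" for m in f.means),
            "sds_ms": ";".join(f"{s:.6g}" for s in f.sds),
            "loglik": f.loglik,
            "threshold_ms": round(d.crossing.threshold),
            "n_obs": f.n_obs,
        })
    return pd.DataFrame(rows)
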