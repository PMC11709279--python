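"""Pairwise-conditional Granger causality between layer-resolved signals.

For each stimulus condition, layer signals (site-averaged MUA time courses)
are modeled as a vector autoregression (VAR).  The Granger causality from a
source channel to a target channel, conditional on all remaining channels,
is the Geweke log variance ratio

    GC(to ← from | rest) = ln( Σ_reduced[to] / Σ_full[to] )

where Σ_full is the residual variance of the target in the VAR on all
channels and Σ_reduced in the VAR omitting the source (both retain the
conditioning channels and share one model order).  Conditioning out the
joint dependencies of the remaining channels mitigates confounds such as
common inputs.  GC is nonnegative up to estimation noise; small negative
estimates are clamped to zero.

VAR coefficients are ordinary least squares on lagged regressors; the
model order is selected by AIC over 1..max_order.  Multiple trials are
pooled into one regression with no lags crossing trial boundaries, after
per-trial mean removal.

Within one probe placement, GC values are z-scored over all (condition,
layer-pair) entries, and condition contrasts are paired Wilcoxon
signed-rank tests across probes with Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisValidationError, FitError

__all__ = [
    "VarFit",
    "GCResult",
    "fit_var",
    "pairwise_conditional_gc",
    "gc_for_conditions",
    "normalize_gc",
    "contrast_conditions",
]


@dataclass
class VarFit:
    """Ordinary-least-squares VAR fit."""

    order: int
    coeffs: np.ndarray  # (order, k, k); coeffs[l, i, j]: channel j at lag l+1 -> channel i
    intercept: np.ndarray  # (k,)
    resid_cov: np.ndarray  # (k, k), ML estimate
    n_obs: int
    stable: bool
    aic_by_order: Optional[dict] = None


def _as_trials(series) -> List[np.ndarray]:
    if isinstance(series, np.ndarray):
        trials = [series]
    else:
        trials = [np.asarray(t, dtype=float) for t in series]
    out = []
    k = None
    for t in trials:
        t = np.asarray(t, dtype=float)
        if t.ndim != 2:
            raise AnalysisValidationError("each trial must be (n_samples, n_channels)")
        if k is None:
            k = t.shape[1]
        elif t.shape[1] != k:
            raise AnalysisValidationError("trials disagree on channel count")
        out.append(t)
    if k is None or k < 2:
        raise AnalysisValidationError("need at least 2 channels")
    return out


def _detrend(trials: List[np.ndarray]) -> List[np.ndarray]:
    return [t - t.mean(axis=0, keepdims=True) for t in trials]


def _lagged_design(trials: List[np.ndarray], p: int):
    """Stack lagged regressors over trials; lags never cross boundaries."""
    xs, ys = [], []
    for t in trials:
        n = t.shape[0]
        if n <= p:
            continue
        y = t[p:]
        x = np.concatenate([t[p - l : n - l] for l in range(1, p + 1)], axis=1)
        xs.append(x)
        ys.append(y)
    if not xs:
        raise FitError("no trial long enough for the requested order")
    return np.concatenate(xs), np.concatenate(ys)


def _ols_var(trials: List[np.ndarray], p: int):
    x, y = _lagged_design(trials, p)
    x1 = np.concatenate([x, np.ones((len(x), 1))], axis=1)
    beta, _, rank, _ = np.linalg.lstsq(x1, y, rcond=None)
    if rank < x1.shape[1]:
        raise FitError("rank-deficient VAR regressors")
    resid = y - x1 @ beta
    n = len(y)
    sigma = resid.T @ resid / n
    return beta, sigma, n


def _companion_stable(coeffs: np.ndarray) -> bool:
    p, k, _ = coeffs.shape
    comp = np.zeros((k * p, k * p))
    for l in range(p):
        comp[:k, l * k : (l + 1) * k] = coeffs[l]
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


def fit_var(
    series,
    max_order: int = 20,
    order: Optional[int] = None,
    detrend: bool = True,
) -> VarFit:
    """Fit a VAR by OLS, selecting the order by AIC over 1..max_order.

    ``series`` is one (n_samples, n_channels) array or a list of such
    per-trial arrays.  An explicit ``order`` skips selection.
    """
    trials = _as_trials(series)
    if detrend:
        trials = _detrend(trials)
    k = trials[0].shape[1]

    aic_by_order = {}
    if order is None:
        best_p, best_aic = 1, np.inf
        for p in range(1, max_order + 1):
            try:
                _, sigma, n = _ols_var(trials, p)
            except FitError:
                break
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                continue
            aic = n * logdet + 2.0 * p * k * k
            aic_by_order[p] = aic
            if aic < best_aic:
                best_p, best_aic = p, aic
        order = best_p

    beta, sigma, n = _ols_var(trials, order)
    coeffs = np.empty((order, k, k))
    for l in range(order):
        coeffs[l] = beta[l * k : (l + 1) * k].T
    intercept = beta[-1]
    return VarFit(
        order=order,
        coeffs=coeffs,
        intercept=intercept,
        resid_cov=sigma,
        n_obs=n,
        stable=_companion_stable(coeffs),
        aic_by_order=aic_by_order or None,
    )


def pairwise_conditional_gc(
    series,
    order: Optional[int] = None,
    max_order: int = 20,
    detrend: bool = True,
    channel_names: Optional[Sequence[str]] = None,
):
    """Pairwise-conditional GC matrix for one condition.

    Returns ``(gc, var_fit)`` where ``gc[i, j]`` is the causality from
    channel j to channel i given all remaining channels; the diagonal is
    NaN.  Full and reduced regressions share the full model's order.
    """
    trials = _as_trials(series)
    if detrend:
        trials = _detrend(trials)
    k = trials[0].shape[1]
    full = fit_var(trials, max_order=max_order, order=order, detrend=False)
    p = full.order
    gc = np.full((k, k), np.nan)
    for j in range(k):  # source
        keep = [c for c in range(k) if c != j]
        sub = [t[:, keep] for t in trials]
        if len(keep) >= 2:
            _, sigma_red, _ = _ols_var(sub, p)
            red_var = np.diag(sigma_red)
        else:
            # single remaining channel: univariate AR
            x, y = _lagged_design([t[:, keep] for t in trials], p)
            x1 = np.concatenate([x, np.ones((len(x), 1))], axis=1)
            beta, *_ = np.linalg.lstsq(x1, y, rcond=None)
            r = y - x1 @ beta
            red_var = np.array([float(np.sum(r * r)) / len(r)])
        for pos, i in enumerate(keep):  # target
            full_var = full.resid_cov[i, i]
            if full_var <= 0:
                raise FitError("singular full-model residual covariance")
            gc[i, j] = max(0.0, math.log(red_var[pos] / full_var))
    return gc, full


@dataclass
class GCResult:
    """Condition-resolved pairwise-conditional GC for one probe."""

    conditions: list
    channel_names: list
    gc: np.ndarray  # (n_conditions, k, k), diagonal NaN
    normalized_gc: np.ndarray  # z-scored over all finite entries
    model_order: int
    var_coefficients: Dict[str, np.ndarray] = field(default_factory=dict)


def normalize_gc(gc: np.ndarray) -> np.ndarray:
    """Z-score over all finite (condition, layer-pair) entries."""
    flat = gc[np.isfinite(gc)]
    mu, sd = flat.mean(), flat.std(ddof=0)
    if sd == 0:
        return np.where(np.isfinite(gc), 0.0, np.nan)
    return (gc - mu) / sd


def gc_for_conditions(
    series_by_condition: Dict,
    order: Optional[int] = None,
    max_order: int = 20,
    channel_names: Optional[Sequence[str]] = None,
) -> GCResult:
    """Compute and z-score GC matrices for several stimulus conditions.

    ``series_by_condition`` maps a condition label to a time series (or
    list of trials) with a shared channel layout.
    """
    conditions = list(series_by_condition)
    mats, coeffs = [], {}
    model_order = 0
    for cond in conditions:
        gc, fit = pairwise_conditional_gc(
            series_by_condition[cond], order=order, max_order=max_order
        )
        mats.append(gc)
        coeffs[str(cond)] = fit.coeffs
        model_order = max(model_order, fit.order)
    gc_arr = np.stack(mats)
    k = gc_arr.shape[1]
    names = list(channel_names) if channel_names else [f"ch{i}" for i in range(k)]
    return GCResult(
        conditions=conditions,
        channel_names=names,
        gc=gc_arr,
        normalized_gc=normalize_gc(gc_arr),
        model_order=model_order,
        var_coefficients=coeffs,
    )


def contrast_conditions(gc_a, gc_b, n_comparisons: int):
    """Contrast normalized GC between two conditions across probes.

    ``gc_a`` and ``gc_b`` are (n_probes, k, k) arrays of normalized GC for
    matched layer pairs.  Returns ``(diff, p_corrected)``: the mean paired
    difference a − b per layer pair and its Bonferroni-corrected Wilcoxon
    signed-rank p value (multiplied by ``n_comparisons``, capped at 1).
    """
    a = np.asarray(gc_a, dtype=float)
    b = np.asarray(gc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise AnalysisValidationError("need matched (n_probes, k, k) arrays")
    k = a.shape[1]
    diff = np.full((k, k), np.nan)
    pcorr = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            x = a[:, i, j]
            y = b[:, i, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() == 0:
                continue
            d = x[ok] - y[ok]
            diff[i, j] = d.mean()
            if np.allclose(d, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(d).pvalue)
            pcorr[i, j] = min(1.0, p * n_comparisons)
    return diff, pcorr
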