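"""Interlaminar gain-transmission models and their comparison.

Signal transmission from the input layers (L4, L6) to the output layers
(L2/3, L5) is modeled as a linear gain followed by a static nonlinearity.
Four variants span the tuned/untuned axis:

* Model I  (untuned gain):  R̂_out(S, i) = f(w · R_in(S, i))
* Model II (tuned gain):    R̂_out(S, i) = f(w(S) · R_in(S, i))
* Model III (tuned gain, untuned suppression):
                            R̂_out(S, i) = [w(S) · R_in(S, i) − T]₊
* Model IV (untuned gain, tuned suppression):
                            R̂_out(S, i) = [w · R_in(S, i) − T(S)]₊

where S runs over stimulus conditions (grating directions plus the blank),
i over repetitions, and R_in(S, i) is the response averaged across the
valid input-layer sites at repetition i.  The smooth threshold-linear
nonlinearity

    f(g) = (A(g−g0)/2)·(1 + erf((g−g0)/(√2·σ)))
         + (A·σ/√(2π))·exp(−(g−g0)²/(2σ²))

is the exact Gaussian expectation A·E[max(g + ε − g0, 0)], ε ~ N(0, σ²),
and converges to A·max(g − g0, 0) as σ → 0.  A power-law alternative
f(g) = A·[g − g0]₊ⁿ is also provided.

Parameters are fitted by bounded least squares minimizing the residual
J = Σ_S Σ_i (R̂_out − R_out)² with seeded multi-start.  Because w and A
multiply through f (the map (w, g0, σ) → (cw, cg0, cσ), A → A/c leaves
predictions unchanged), the tuned-gain models are reported with the mean
gain over grating conditions normalized to 1; the gain tuning shape and
its DSI are invariant to this choice.  Models are compared with an
adjusted goodness of fit, AIC, and BIC, all penalizing parameter count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .errors import AnalysisValidationError, FitError, UndefinedStatisticError

__all__ = [
    "NonlinearityParams",
    "GainModelFit",
    "ResponseRatioTuning",
    "threshold_linear",
    "power_law",
    "relu",
    "apply_nonlinearity",
    "fit_gain_model",
    "adjusted_r2",
    "aic_bic",
    "contribution_decomposition",
    "response_ratio_tuning",
    "gain_dsi",
]

MODELS = ("I", "II", "III", "IV")
FAMILIES = ("threshold_linear", "power_law", "relu")


@dataclass(frozen=True)
class NonlinearityParams:
    """Static nonlinearity parameters.

    ``A`` is the gain (≥ 0), ``g0`` the threshold; ``sigma`` (> 0) controls
    the smoothness of the threshold-linear transition; ``n`` (> 0) is the
    power-law exponent.
    """

    family: str
    A: float
    g0: float
    sigma: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise AnalysisValidationError(f"unknown family {self.family!r}")
        if self.A < 0:
            raise AnalysisValidationError("A must be nonnegative")
        if self.family == "threshold_linear":
            if self.sigma is None or self.sigma <= 0:
                raise AnalysisValidationError("threshold_linear needs sigma > 0")
        if self.family == "power_law":
            if self.n is None or self.n <= 0:
                raise AnalysisValidationError("power_law needs n > 0")


def threshold_linear(g, params: NonlinearityParams) -> np.ndarray:
    """Smooth threshold-linear nonlinearity (Gaussian-smoothed ReLU)."""
    if params.family != "threshold_linear":
        raise AnalysisValidationError("params are not threshold_linear")
    return _threshold_linear(np.asarray(g, dtype=float), params.A, params.g0, params.sigma)


def _threshold_linear(g, A, g0, sigma):
    z = g - g0
    return (A * z / 2.0) * (1.0 + erf(z / (math.sqrt(2.0) * sigma))) + (
        A * sigma / math.sqrt(2.0 * math.pi)
    ) * np.exp(-(z**2) / (2.0 * sigma**2))


def power_law(g, params: NonlinearityParams) -> np.ndarray:
    """Rectified power-law nonlinearity A·[g − g0]₊ⁿ."""
    if params.family != "power_law":
        raise AnalysisValidationError("params are not power_law")
    return params.A * np.maximum(np.asarray(g, dtype=float) - params.g0, 0.0) ** params.n


def relu(g, params: NonlinearityParams) -> np.ndarray:
    """Rectified-linear nonlinearity A·[g − g0]₊."""
    if params.family != "relu":
        raise AnalysisValidationError("params are not relu")
    return params.A * np.maximum(np.asarray(g, dtype=float) - params.g0, 0.0)


def apply_nonlinearity(g, params: NonlinearityParams) -> np.ndarray:
    return {"threshold_linear": threshold_linear, "power_law": power_law, "relu": relu}[
        params.family
    ](g, params)


# --------------------------------------------------------------------------
# Fit quality
# --------------------------------------------------------------------------

def adjusted_r2(fitted, observed, n_param: int) -> float:
    """Adjusted goodness of fit penalizing the number of free parameters.

    adjR² = 1 − (N−1)/(N−Np) · 2·Σ(R̂−R)² / (Σ(R̂−R̂̄)² + Σ(R−R̄)²).
    A perfect fit gives exactly 1.
    """
    f = np.asarray(fitted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if f.shape != y.shape:
        raise AnalysisValidationError("fitted and observed must align")
    n = len(y)
    if n <= n_param:
        raise AnalysisValidationError("need more samples than parameters")
    denom = np.sum((f - f.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    if denom == 0:
        raise UndefinedStatisticError("both series constant; adjR² undefined")
    return float(1.0 - (n - 1) / (n - n_param) * 2.0 * np.sum((f - y) ** 2) / denom)


def aic_bic(J: float, n_sample: int, n_param: int) -> tuple:
    """Gaussian-residual AIC and BIC from the residual sum of squares."""
    j = max(float(J), 1e-300)
    ll_term = n_sample * math.log(j / n_sample)
    return ll_term + 2 * n_param, ll_term + math.log(n_sample) * n_param


# --------------------------------------------------------------------------
# Model fitting
# --------------------------------------------------------------------------

@dataclass
class GainModelFit:
    """One fitted interlaminar transmission model."""

    model: str
    family: Optional[str]
    w: np.ndarray  # per-condition gain (length n_conditions)
    T: Optional[np.ndarray]  # per-condition suppression (Models III/IV)
    nonlinearity: Optional[NonlinearityParams]  # Models I/II
    objective_J: float
    n_param: int
    n_sample: int
    adj_r2: float
    aic: float
    bic: float
    fitted_output: np.ndarray  # (n_conditions, n_rep), NaN-padded
    directions: np.ndarray
    blank_index: int

    @property
    def grating_gains(self) -> np.ndarray:
        return np.delete(self.w, self.blank_index)

    def mean_fitted_by_condition(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.fitted_output, axis=1)

    def predict(self, input_rates) -> np.ndarray:
        """Forward pass on per-condition-and-repetition input rates."""
        g = self.w[:, None] * np.asarray(input_rates, dtype=float)
        if self.model in ("I", "II"):
            return apply_nonlinearity(g, self.nonlinearity)
        return np.maximum(g - self.T[:, None], 0.0)


def _pair_by_trial(input_rates, output_rates):
    """Align (condition, repetition) samples, truncating to the common
    minimum repetition count per condition."""
    a = np.asarray(input_rates, dtype=float)
    b = np.asarray(output_rates, dtype=float)
    if a.shape[0] != b.shape[0] or a.ndim != 2 or b.ndim != 2:
        raise AnalysisValidationError(
            "input and output rates must be (n_conditions, n_rep) arrays"
        )
    n_cond = a.shape[0]
    pairs_in, pairs_out, counts = [], [], []
    for c in range(n_cond):
        ra = a[c][np.isfinite(a[c])]
        rb = b[c][np.isfinite(b[c])]
        n = min(len(ra), len(rb))
        if n < 2:
            raise AnalysisValidationError(
                f"condition {c} has fewer than 2 paired repetitions"
            )
        pairs_in.append(ra[:n])
        pairs_out.append(rb[:n])
        counts.append(n)
    return pairs_in, pairs_out, np.array(counts)


def _nl_param_layout(family):
    # (names, count) of nonlinearity parameters in the optimization vector
    if family == "threshold_linear":
        return 3
    if family == "power_law":
        return 3
    if family == "relu":
        return 2
    raise AnalysisValidationError(f"unknown family {family!r}")


def fit_gain_model(
    input_rates,
    output_rates,
    model: str,
    family: str = "threshold_linear",
    directions=None,
    blank_index: int = -1,
    seeds: Sequence[int] = tuple(range(10)),
) -> GainModelFit:
    """Fit one transmission model to layer-averaged paired rates.

    Parameters
    ----------
    input_rates, output_rates : ndarray, shape (n_conditions, n_rep)
        Layer-averaged rates per condition and repetition (NaN-padded);
        samples are paired by trial index within condition and truncated to
        the common minimum repetition count.
    model : {"I", "II", "III", "IV"}
    family : nonlinearity family for Models I/II (ignored for III/IV,
        whose nonlinearity is the ReLU by construction).
    directions : grating directions in degrees (defaults to an even grid);
        used only for bookkeeping and gain-DSI extraction.
    blank_index : index of the blank condition (default: last).
    seeds : integers seeding the multi-start perturbations; the best
        objective is kept.
    """
    if model not in MODELS:
        raise AnalysisValidationError(f"unknown model {model!r}")
    xs_in, xs_out, counts = _pair_by_trial(input_rates, output_rates)
    n_cond = len(xs_in)
    blank_index = blank_index % n_cond
    g_in = np.concatenate(xs_in)
    y = np.concatenate(xs_out)
    cond_of = np.repeat(np.arange(n_cond), counts)
    n_sample = len(y)
    if np.all(g_in == 0):
        raise FitError("all-zero input rates; transmission model degenerate")
    if directions is None:
        n_grat = n_cond - 1
        directions = np.arange(n_grat) * (360.0 / n_grat)
    directions = np.asarray(directions, dtype=float)

    gmax = float(max(g_in.max(), 1.0))
    ymax = float(max(y.max(), 1.0))
    ratio0 = ymax / gmax

    if model in ("I", "II"):
        n_nl = _nl_param_layout(family)
        n_w = n_cond if model == "II" else 0
        n_param = n_nl + (n_w - 1 if model == "II" else 0)
    else:
        family = None
        if model == "III":
            n_w, n_t = n_cond, 1
        else:
            n_w, n_t = 1, n_cond
        n_param = n_w + n_t
    if n_sample <= n_param:
        raise FitError(
            f"underdetermined: {n_sample} samples for {n_param} parameters"
        )

    def predict_vec(x):
        if model == "I":
            nlp = x[:3] if family != "relu" else x[:2]
            drive = g_in
        elif model == "II":
            k = 3 if family != "relu" else 2
            nlp, w = x[:k], x[k:]
            drive = w[cond_of] * g_in
        elif model == "III":
            t, w = x[0], x[1:]
            return np.maximum(w[cond_of] * g_in - t, 0.0)
        else:  # IV
            w, t = x[0], x[1:]
            return np.maximum(w * g_in - t[cond_of], 0.0)
        if family == "threshold_linear":
            return _threshold_linear(drive, nlp[0], nlp[1], max(nlp[2], 1e-9))
        if family == "power_law":
            return nlp[0] * np.maximum(drive - nlp[1], 0.0) ** nlp[2]
        return nlp[0] * np.maximum(drive - nlp[1], 0.0)

    def resid(x):
        return predict_vec(x) - y

    # base start: per-condition output/input mean ratio as the gain guess
    mean_in = np.array([v.mean() for v in xs_in])
    mean_out = np.array([v.mean() for v in xs_out])
    with np.errstate(divide="ignore", invalid="ignore"):
        w_guess = np.where(mean_in > 0, mean_out / np.maximum(mean_in, 1e-12), ratio0)
    w_guess = np.clip(w_guess, 1e-3, None)

    def start_bounds(rng=None):
        jitter = (lambda v: v * rng.uniform(0.5, 2.0)) if rng is not None else (lambda v: v)
        if model in ("I", "II"):
            A0 = jitter(float(np.median(w_guess)) if model == "I" else 1.0)
            g00 = 0.0 if rng is None else rng.uniform(-0.2, 0.2) * gmax
            if family == "threshold_linear":
                nl0 = [A0, g00, jitter(0.1 * gmax)]
                nl_lo = [1e-6, -gmax, 1e-3]
                nl_hi = [100.0, gmax, gmax]
            elif family == "power_law":
                nl0 = [A0, g00, jitter(1.0)]
                nl_lo = [1e-6, -gmax, 0.5]
                nl_hi = [100.0, gmax, 5.0]
            else:
                nl0 = [A0, g00]
                nl_lo = [1e-6, -gmax]
                nl_hi = [100.0, gmax]
            if model == "I":
                return np.array(nl0), (np.array(nl_lo), np.array(nl_hi))
            w0 = w_guess if rng is None else w_guess * rng.uniform(0.7, 1.4, n_cond)
            x0 = np.concatenate([nl0, w0])
            lo = np.concatenate([nl_lo, np.zeros(n_cond)])
            hi = np.concatenate([nl_hi, np.full(n_cond, 100.0 * max(ratio0, 1.0))])
            return x0, (lo, hi)
        if model == "III":
            t0 = 0.0 if rng is None else rng.uniform(0.0, 0.2) * ymax
            w0 = w_guess if rng is None else w_guess * rng.uniform(0.7, 1.4, n_cond)
            x0 = np.concatenate([[t0], w0])
            lo = np.concatenate([[-ymax], np.zeros(n_cond)])
            hi = np.concatenate([[ymax], np.full(n_cond, 100.0 * max(ratio0, 1.0))])
            return x0, (lo, hi)
        # IV
        wbar = float(np.median(w_guess)) if rng is None else float(
            np.median(w_guess)
        ) * rng.uniform(0.5, 2.0)
        t0 = np.zeros(n_cond) if rng is None else rng.uniform(0.0, 0.2, n_cond) * ymax
        x0 = np.concatenate([[wbar], t0])
        lo = np.concatenate([[1e-6], np.full(n_cond, -ymax)])
        hi = np.concatenate([[100.0 * max(ratio0, 1.0)], np.full(n_cond, ymax)])
        return x0, (lo, hi)

    best = None
    starts = [start_bounds()]
    for s in seeds:
        starts.append(start_bounds(np.random.default_rng(int(s))))
    for x0, (lo, hi) in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all optimization starts failed")

    x = best.x
    J = float(2.0 * best.cost)
    fitted_flat = predict_vec(x)

    # unpack, applying the scale normalization for Model II
    T = None
    nl = None
    if model == "I":
        w_full = np.ones(n_cond)
        if family == "threshold_linear":
            nl = NonlinearityParams(family, x[0], x[1], sigma=max(x[2], 1e-9))
        elif family == "power_law":
            nl = NonlinearityParams(family, x[0], x[1], n=x[2])
        else:
            nl = NonlinearityParams(family, x[0], x[1])
    elif model == "II":
        k = 3 if family != "relu" else 2
        w_full = x[k:].copy()
        A, g0 = x[0], x[1]
        grating = np.delete(w_full, blank_index)
        c = float(grating.mean())
        if c > 0:
            # w' = w/c shrinks the drive by c; the exact compensation is
            # A' = A·c, g0' = g0/c, σ' = σ/c (power law: A' = A·cⁿ)
            w_full = w_full / c
            if family == "threshold_linear":
                nl = NonlinearityParams(family, A * c, g0 / c, sigma=max(x[2] / c, 1e-9))
            elif family == "power_law":
                nl = NonlinearityParams(family, A * c**x[2], g0 / c, n=x[2])
            else:
                nl = NonlinearityParams(family, A * c, g0 / c)
        else:
            if family == "threshold_linear":
                nl = NonlinearityParams(family, A, g0, sigma=max(x[2], 1e-9))
            elif family == "power_law":
                nl = NonlinearityParams(family, A, g0, n=x[2])
            else:
                nl = NonlinearityParams(family, A, g0)
    elif model == "III":
        T = np.full(n_cond, x[0])
        w_full = x[1:].copy()
    else:
        w_full = np.full(n_cond, x[0])
        T = x[1:].copy()

    fitted = np.full((n_cond, int(counts.max())), np.nan)
    off = 0
    for c, n in enumerate(counts):
        fitted[c, :n] = fitted_flat[off : off + n]
        off += n

    adj = adjusted_r2(fitted_flat, y, n_param)
    aic, bic = aic_bic(J, n_sample, n_param)
    return GainModelFit(
        model=model,
        family=family,
        w=w_full,
        T=T,
        nonlinearity=nl,
        objective_J=J,
        n_param=n_param,
        n_sample=n_sample,
        adj_r2=adj,
        aic=aic,
        bic=bic,
        fitted_output=fitted,
        directions=directions,
        blank_index=blank_index,
    )


def gain_dsi(fit: GainModelFit) -> float:
    """DSI of the fitted gain curve over grating directions.

    Preferred = direction of maximum gain; null = measured direction
    nearest 180° opposite.
    """
    w = fit.grating_gains
    d = np.mod(fit.directions, 360.0)
    if len(w) != len(d):
        raise AnalysisValidationError("directions do not match grating gains")
    ip = int(np.argmax(w))
    null = (d[ip] + 180.0) % 360.0
    inull = int(np.argmin(np.abs(((d - null) + 180.0) % 360.0 - 180.0)))
    wp, wn = float(w[ip]), float(w[inull])
    if wp + wn <= 0:
        raise UndefinedStatisticError("gain DSI undefined: wp + wn <= 0")
    return (wp - wn) / (wp + wn)


# --------------------------------------------------------------------------
# Contribution decomposition and response ratios
# --------------------------------------------------------------------------

def contribution_decomposition(
    dsi_input: float, dsi_output: float, dsi_model1: float, dsi_model2: float
) -> tuple:
    """Split the interlaminar DSI enhancement into nonlinearity and
    tuned-gain contributions.

    contrib_nonlin = (DSI_ModelI − DSI_in) / (DSI_out − DSI_in)
    contrib_gain   = (DSI_ModelII − DSI_ModelI) / (DSI_out − DSI_in)
    """
    denom = dsi_output - dsi_input
    if denom == 0:
        raise UndefinedStatisticError("no DSI enhancement; contributions undefined")
    return (dsi_model1 - dsi_input) / denom, (dsi_model2 - dsi_model1) / denom


@dataclass
class ResponseRatioTuning:
    """Output/input response ratio per condition, aligned to 90°."""

    aligned_directions: np.ndarray  # degrees; preferred mapped to 90
    ratio: np.ndarray  # per grating condition (NaN where input <= 0)
    ratio_blank: float
    ratio_null: float
    ratio_pref: float


def response_ratio_tuning(
    input_means,
    output_means,
    directions,
    theta_pref: float,
    blank_index: int = -1,
) -> ResponseRatioTuning:
    """Ratio of output-layer to input-layer response per condition.

    The direction axis is circularly shifted so the preferred direction
    maps to 90°; ratios are masked (NaN) where the input response is not
    positive.
    """
    a = np.asarray(input_means, dtype=float)
    b = np.asarray(output_means, dtype=float)
    d = np.asarray(directions, dtype=float)
    if a.shape != b.shape:
        raise AnalysisValidationError("input and output means must align")
    n_cond = len(a)
    blank_index = blank_index % n_cond
    grat = np.delete(np.arange(n_cond), blank_index)
    if len(grat) != len(d):
        raise AnalysisValidationError("directions do not match grating conditions")
    with np.errstate(divide="ignore", invalid="ignore"):
        full_ratio = np.where(a > 0, b / np.where(a > 0, a, 1.0), np.nan)
    ratio = full_ratio[grat]
    aligned = np.mod(d - theta_pref + 90.0, 360.0)
    ip = int(np.argmin(np.abs(((d - theta_pref) + 180.0) % 360.0 - 180.0)))
    null_dir = (theta_pref + 180.0) % 360.0
    inull = int(np.argmin(np.abs(((d - null_dir) + 180.0) % 360.0 - 180.0)))
    return ResponseRatioTuning(
        aligned_directions=aligned,
        ratio=ratio,
        ratio_blank=float(full_ratio[blank_index]),
        ratio_null=float(ratio[inull]),
        ratio_pref=float(ratio[ip]),
    )
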