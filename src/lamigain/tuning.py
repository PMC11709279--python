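"""Direction and orientation tuning: von Mises fits and selectivity indices.

Direction tuning of the time-averaged response R(θ) is modeled as a sum of
two von Mises lobes with a shared normalization, one at the preferred
direction and one at the null direction (always 180° opposite)::

    R(θ) = α · V(θ − θ_pref; σ1) + β · V(θ − θ_null; σ2) + R0
    V(x; σ) = (exp(σ·cos x) − exp(−σ)) / (exp(σ) − exp(−σ))

V peaks at 1 when x = 0 and reaches 0 at x = 180°, so α and β are the lobe
heights above the offset R0, and σ1, σ2 set the tuning widths.  Orientation
tuning uses a single lobe with angle doubling (period 180°).

The direction selectivity index DSI = (R_pref − R_null)/(R_pref + R_null)
and the orientation selectivity index OSI (with the orthogonal orientation
in place of the null) are computed from the fitted curve by default.
DSI = 1/3 corresponds to a preferred response twice the null response.

Angles are degrees at every interface; trigonometry is done in radians
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisValidationError, FitError, UndefinedStatisticError

__all__ = [
    "DirectionTuningFit",
    "OrientationTuningFit",
    "TuningSummary",
    "von_mises_direction",
    "von_mises_orientation",
    "fit_direction_tuning",
    "fit_orientation_tuning",
    "compute_dsi",
    "compute_osi",
    "raw_dsi",
    "compute_f1f0",
    "preferred_direction_difference",
    "classify_direction_pair",
]

_SIGMA_BOUNDS = (1e-3, 50.0)


def _vm_lobe(delta_rad: np.ndarray, sigma: float) -> np.ndarray:
    """Normalized von Mises lobe: 1 at delta=0, 0 at delta=pi."""
    return (np.exp(sigma * np.cos(delta_rad)) - np.exp(-sigma)) / (
        np.exp(sigma) - np.exp(-sigma)
    )


def von_mises_direction(
    theta_deg, theta_pref: float, sigma1: float, sigma2: float,
    alpha: float, beta: float, r0: float,
) -> np.ndarray:
    """Two-lobe direction tuning curve evaluated at ``theta_deg``."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    tp = math.radians(theta_pref)
    return (
        alpha * _vm_lobe(th - tp, sigma1)
        + beta * _vm_lobe(th - tp - math.pi, sigma2)
        + r0
    )


def von_mises_orientation(
    theta_deg, theta_pref: float, sigma1: float, alpha: float, r0: float
) -> np.ndarray:
    """Single-lobe, angle-doubled orientation tuning curve."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    tp = math.radians(theta_pref)
    return alpha * _vm_lobe(2.0 * (th - tp), sigma1) + r0


@dataclass
class DirectionTuningFit:
    theta_pref: float  # degrees in [0, 360)
    sigma1: float
    sigma2: float
    alpha: float
    beta: float
    r0: float
    residual: float  # sum of squared residuals
    converged: bool
    message: str = ""

    @property
    def theta_null(self) -> float:
        return (self.theta_pref + 180.0) % 360.0

    def predict(self, theta_deg) -> np.ndarray:
        return von_mises_direction(
            theta_deg, self.theta_pref, self.sigma1, self.sigma2,
            self.alpha, self.beta, self.r0,
        )

    @property
    def r_pref(self) -> float:
        return float(self.predict(self.theta_pref))

    @property
    def r_null(self) -> float:
        return float(self.predict(self.theta_null))


@dataclass
class OrientationTuningFit:
    theta_pref: float  # degrees in [0, 180)
    sigma1: float
    alpha: float
    r0: float
    residual: float
    converged: bool
    message: str = ""

    @property
    def theta_ortho(self) -> float:
        return (self.theta_pref + 90.0) % 180.0

    def predict(self, theta_deg) -> np.ndarray:
        return von_mises_orientation(
            theta_deg, self.theta_pref, self.sigma1, self.alpha, self.r0
        )

    @property
    def r_pref(self) -> float:
        return float(self.predict(self.theta_pref))

    @property
    def r_ortho(self) -> float:
        return float(self.predict(self.theta_ortho))

    @property
    def hwhh(self) -> float:
        """Half-width at half-height of the fitted lobe, degrees.

        Closed form: the lobe falls to half its height above R0 where
        cos(2Δ) = ln(cosh σ1)/σ1.
        """
        c = math.log(math.cosh(self.sigma1)) / self.sigma1
        return math.degrees(math.acos(max(-1.0, min(1.0, c)))) / 2.0

    @property
    def op_ratio(self) -> float:
        """Orthogonal-to-preferred response ratio R(ortho)/R(pref)."""
        if self.r_pref == 0:
            raise UndefinedStatisticError("zero preferred response")
        return self.r_ortho / self.r_pref


@dataclass
class TuningSummary:
    dsi: Optional[float] = None
    osi: Optional[float] = None
    f1f0: Optional[float] = None
    r_pref: Optional[float] = None
    r_null: Optional[float] = None
    r_ortho: Optional[float] = None


def _check_fit_inputs(responses, directions, n_params: int):
    r = np.asarray(responses, dtype=float)
    d = np.asarray(directions, dtype=float)
    if r.shape != d.shape or r.ndim != 1:
        raise AnalysisValidationError("responses and directions must be 1-D and aligned")
    if not np.all(np.isfinite(r)):
        raise AnalysisValidationError("responses must be finite")
    if len(np.unique(np.mod(d, 360.0))) < 6:
        raise AnalysisValidationError("need at least 6 distinct directions")
    if len(r) < n_params:
        raise FitError("fewer observations than parameters")
    return r, d


def fit_direction_tuning(responses, directions) -> DirectionTuningFit:
    """Least-squares fit of the two-lobe direction tuning curve.

    Initial guesses: θ_pref at the direction of maximum response (lowest
    index on ties), σ1 = σ2 = 1, α = β = max − min, R0 = min.  Bounds:
    σ ∈ (1e-3, 50], α, β ≥ 0; θ_pref free within ±180° of the guess.
    """
    r, d = _check_fit_inputs(responses, directions, 6)
    i0 = int(np.argmax(r))
    rng_amp = float(r.max() - r.min())
    x0 = np.array([d[i0], 1.0, 1.0, rng_amp, rng_amp, float(r.min())])

    def resid(x):
        return von_mises_direction(d, *x) - r

    lo = [x0[0] - 180.0, _SIGMA_BOUNDS[0], _SIGMA_BOUNDS[0], 0.0, 0.0, -np.inf]
    hi = [x0[0] + 180.0, _SIGMA_BOUNDS[1], _SIGMA_BOUNDS[1], np.inf, np.inf, np.inf]
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    fit = DirectionTuningFit(
        theta_pref=float(np.mod(sol.x[0], 360.0)),
        sigma1=float(sol.x[1]),
        sigma2=float(sol.x[2]),
        alpha=float(sol.x[3]),
        beta=float(sol.x[4]),
        r0=float(sol.x[5]),
        residual=float(2.0 * sol.cost),
        converged=bool(sol.success),
        message=sol.message,
    )
    # the fit must not be worse than its own starting point
    init_res = float(np.sum(resid(x0) ** 2))
    if fit.residual > init_res + 1e-9:
        fit = DirectionTuningFit(
            theta_pref=float(np.mod(x0[0], 360.0)), sigma1=1.0, sigma2=1.0,
            alpha=rng_amp, beta=rng_amp, r0=float(r.min()),
            residual=init_res, converged=False,
            message="optimizer failed to improve on the initial guess",
        )
    return fit


def fit_orientation_tuning(responses, directions) -> OrientationTuningFit:
    """Least-squares fit of the angle-doubled orientation tuning curve."""
    r, d = _check_fit_inputs(responses, directions, 4)
    i0 = int(np.argmax(r))
    x0 = np.array([d[i0], 1.0, float(r.max() - r.min()), float(r.min())])

    def resid(x):
        return von_mises_orientation(d, *x) - r

    lo = [x0[0] - 90.0, _SIGMA_BOUNDS[0], 0.0, -np.inf]
    hi = [x0[0] + 90.0, _SIGMA_BOUNDS[1], np.inf, np.inf]
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    return OrientationTuningFit(
        theta_pref=float(np.mod(sol.x[0], 180.0)),
        sigma1=float(sol.x[1]),
        alpha=float(sol.x[2]),
        r0=float(sol.x[3]),
        residual=float(2.0 * sol.cost),
        converged=bool(sol.success),
        message=sol.message,
    )


def compute_dsi(fit: DirectionTuningFit) -> TuningSummary:
    """DSI = (R_pref − R_null)/(R_pref + R_null) from the fitted curve."""
    rp, rn = fit.r_pref, fit.r_null
    if rp + rn <= 0:
        raise UndefinedStatisticError(
            "DSI undefined: fitted preferred + null response is not positive"
        )
    return TuningSummary(dsi=(rp - rn) / (rp + rn), r_pref=rp, r_null=rn)


def compute_osi(fit: OrientationTuningFit) -> TuningSummary:
    """OSI = (R_pref − R_ortho)/(R_pref + R_ortho) from the fitted curve."""
    rp, ro = fit.r_pref, fit.r_ortho
    if rp + ro <= 0:
        raise UndefinedStatisticError(
            "OSI undefined: fitted preferred + orthogonal response is not positive"
        )
    return TuningSummary(osi=(rp - ro) / (rp + ro), r_pref=rp, r_ortho=ro)


def raw_dsi(responses, directions) -> float:
    """DSI from raw per-direction means: preferred at argmax, null 180° away.

    Offered as an alternative to the fitted-curve default; the null response
    is taken at the measured direction closest to θ_pref + 180°.
    """
    r = np.asarray(responses, dtype=float)
    d = np.mod(np.asarray(directions, dtype=float), 360.0)
    ip = int(np.argmax(r))
    null = (d[ip] + 180.0) % 360.0
    inull = int(np.argmin(np.abs(((d - null) + 180.0) % 360.0 - 180.0)))
    rp, rn = r[ip], r[inull]
    if rp + rn <= 0:
        raise UndefinedStatisticError("raw DSI undefined")
    return float((rp - rn) / (rp + rn))


def compute_f1f0(psth, time_s, tf_hz: float) -> float:
    """Response modulation ratio F1/F0 of a trial-averaged time course.

    F1 is the amplitude of the Fourier component at the stimulus temporal
    frequency; F0 is the mean rate.  Cells with F1/F0 ≥ 1 are classified
    simple, < 1 complex.
    """
    r = np.asarray(psth, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if r.shape != t.shape:
        raise AnalysisValidationError("psth and time axes must align")
    duration = t[-1] - t[0]
    if duration * tf_hz < 2.0:
        raise AnalysisValidationError("need at least 2 stimulus cycles")
    f0 = float(np.mean(r))
    if f0 == 0:
        raise UndefinedStatisticError("F0 is zero; modulation ratio undefined")
    f1 = 2.0 * abs(np.mean(r * np.exp(-2j * np.pi * tf_hz * t)))
    return float(f1 / abs(f0))


def preferred_direction_difference(theta_a: float, theta_b: float) -> float:
    """Minimal circular distance of two directions, folded to [0, 180]."""
    d = abs((theta_a - theta_b) % 360.0)
    return min(d, 360.0 - d)


def classify_direction_pair(theta_a: float, theta_b: float) -> str:
    """Bin a pair: 'maintained' (<30°), 'reversed' (>150°), else 'other'."""
    d = preferred_direction_difference(theta_a, theta_b)
    if d < 30.0:
        return "maintained"
    if d > 150.0:
        return "reversed"
    return "other"
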