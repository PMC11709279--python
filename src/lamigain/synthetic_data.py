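"""Synthetic laminar probes with known ground truth.

The generator emulates one perpendicular probe placement in early visual
cortex: direction-tuned input-layer sites (L4/L6) whose two-lobe von Mises
tuning drives output-layer sites (L2/3, L5) through a direction-tuned
linear gain and a static threshold-linear nonlinearity, with a latency
offset between layers and trial-to-trial noise.  Every downstream stage of
the pipeline can therefore be tested against the planted parameters.

Study conditions baked into the defaults: 12 equally spaced drift
directions, 10 repetitions per direction, blank trials ≈ 10 % of all
trials, output-layer latency ≈ 51.8 ms vs input-layer ≈ 38.6 ms, and
trial noise with Poisson-like variance scaling (Gaussian on rates, sd
proportional to √mean).

The gain curve over directions is w(θ) = w̄·(1 + m·cos(θ − θ_pref)), so
the gain DSI (w_pref − w_null)/(w_pref + w_null) equals m exactly; the
blank gain sits below the null-direction gain, w(blank) = w̄·(1 − 1.1·m).
An "untuned" gain is constant across every condition including the blank.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .data_model_io import TrialResponseTable
from .errors import AnalysisValidationError
from .gain_models import NonlinearityParams, apply_nonlinearity
from .tuning import von_mises_direction

__all__ = [
    "GroundTruth",
    "SyntheticProbeDataset",
    "make_ground_truth",
    "simulate_probe",
    "simulate_coupled_timeseries",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG: Dict = {
    "n_directions": 12,
    "n_reps": 10,
    "blank_fraction": 0.10,
    "gain_mode": "tuned",  # "tuned" | "untuned"
    "gain_dsi": 0.3,
    # mean grating gain chosen so that, with the default nonlinearity, the
    # output/input response ratio is ~1 in the preferred direction and < 1
    # in the null direction and under the blank (preferred response
    # preserved, others attenuated)
    "gain_base": 0.85,
    "input_peak_rate": 25.0,  # spikes/s, preferred-lobe height above offset
    "input_offset": 5.0,  # spikes/s, von Mises offset R0 (≈ blank response)
    "input_dsi": 0.25,
    "sigma1": 1.5,
    "sigma2": 1.5,
    "theta_pref": None,  # degrees; None -> drawn uniformly
    "theta_jitter_deg": 5.0,  # per-site jitter of the preferred direction
    "nonlinearity": {"family": "threshold_linear", "A": 1.0, "g0": 2.0, "sigma": 2.0},
    "latency_by_layer": {"L2/3": 51.8, "L4": 38.6, "L5": 51.8, "L6": 38.6},
    "noise_model": {"kind": "gaussian_sqrt", "scale": 1.0},
    "coupled_trials": True,
    "output_noise_scale": 1.0,
    "psth_window_ms": (-100.0, 300.0),
    "bin_ms": 2.0,
    "latency_rise_ms": 6.0,
}

_RANGES = {
    "n_directions": (6, 24),
    "n_reps": (2, 100),
    "blank_fraction": (0.0, 0.5),
    "gain_dsi": (0.0, 0.8),
}


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic probe."""

    directions: np.ndarray  # degrees, gratings only
    theta_pref: float  # population preferred direction, degrees
    input_tuning: List[dict]  # per-input-site von Mises parameters
    gain_curve: np.ndarray  # w(S), length n_directions + 1 (blank last)
    gain_dsi: float
    nonlinearity: NonlinearityParams
    latency_by_layer: Dict[str, float]
    noise_model: dict
    blank_fraction: float
    n_reps: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def blank_index(self) -> int:
        return len(self.gain_curve) - 1

    def input_site_means(self) -> np.ndarray:
        """Noise-free mean rates of input sites, (n_input, n_cond)."""
        n_cond = len(self.directions) + 1
        out = np.empty((len(self.input_tuning), n_cond))
        for i, p in enumerate(self.input_tuning):
            out[i, :-1] = von_mises_direction(
                self.directions, p["theta_pref"], p["sigma1"], p["sigma2"],
                p["alpha"], p["beta"], p["r0"],
            )
            out[i, -1] = p["r0"]  # blank: spontaneous level
        return out

    def output_means(self) -> np.ndarray:
        """Noise-free output-layer means f(w(S)·input mean), (n_cond,)."""
        m = self.input_site_means().mean(axis=0)
        return apply_nonlinearity(self.gain_curve * m, self.nonlinearity)

    def to_json(self) -> str:
        d = {
            "directions": self.directions.tolist(),
            "theta_pref": self.theta_pref,
            "input_tuning": self.input_tuning,
            "gain_curve": self.gain_curve.tolist(),
            "gain_dsi": self.gain_dsi,
            "nonlinearity": asdict(self.nonlinearity),
            "latency_by_layer": self.latency_by_layer,
            "noise_model": self.noise_model,
            "blank_fraction": self.blank_fraction,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


@dataclass
class SyntheticProbeDataset:
    table: TrialResponseTable
    truth: GroundTruth
    layer_labels: List[str]  # true layer per site


def make_ground_truth(config: Optional[dict] = None, seed: int = 0) -> GroundTruth:
    """Draw a deterministic ground truth from a configuration.

    Unknown keys and out-of-range values raise a validation error naming
    the offending keys.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise AnalysisValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    bad = [
        k
        for k, (lo, hi) in _RANGES.items()
        if not (lo <= cfg[k] <= hi)
    ]
    if cfg["gain_mode"] not in ("tuned", "untuned"):
        bad.append("gain_mode")
    if bad:
        raise AnalysisValidationError(f"config values out of range: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    n_dir = int(cfg["n_directions"])
    directions = np.arange(n_dir) * (360.0 / n_dir)
    theta_pref = (
        float(rng.uniform(0.0, 360.0))
        if cfg["theta_pref"] is None
        else float(cfg["theta_pref"]) % 360.0
    )
    # snap the population preference to the measured grid so the planted
    # gain peak coincides with a tested direction
    theta_pref = float(directions[np.argmin(np.abs(
        ((directions - theta_pref) + 180.0) % 360.0 - 180.0))])

    m = float(cfg["gain_dsi"]) if cfg["gain_mode"] == "tuned" else 0.0
    w_base = float(cfg["gain_base"])
    w = w_base * (1.0 + m * np.cos(np.deg2rad(directions - theta_pref)))
    w_blank = w_base * (1.0 - 1.1 * m)
    gain_curve = np.append(w, w_blank)
    if np.any(gain_curve <= 0):
        raise AnalysisValidationError("gain curve must be strictly positive")

    nl_cfg = dict(cfg["nonlinearity"])
    nonlinearity = NonlinearityParams(**nl_cfg)

    # per-site von Mises parameters; beta solves the target input DSI
    # (R_pref − R_null)/(R_pref + R_null) = dsi with R_pref = α + R0,
    # R_null = β + R0 (the opposite lobe vanishes at 180°)
    alpha = float(cfg["input_peak_rate"])
    r0 = float(cfg["input_offset"])
    dsi_in = float(cfg["input_dsi"])
    beta = (alpha * (1.0 - dsi_in) - 2.0 * dsi_in * r0) / (1.0 + dsi_in)
    if beta < 0:
        raise AnalysisValidationError("input_dsi too high for the given offset")
    return GroundTruth(
        directions=directions,
        theta_pref=theta_pref,
        input_tuning=[],  # filled per probe in simulate_probe
        gain_curve=gain_curve,
        gain_dsi=m,
        nonlinearity=nonlinearity,
        latency_by_layer=dict(cfg["latency_by_layer"]),
        noise_model=dict(cfg["noise_model"]),
        blank_fraction=float(cfg["blank_fraction"]),
        n_reps=int(cfg["n_reps"]),
        seed=int(seed),
        config={**cfg, "alpha": alpha, "beta": beta, "r0": r0,
                "theta_pref_snapped": theta_pref},
    )


def _draw_noise(rng, mean, noise_model):
    mean = np.asarray(mean, dtype=float)
    kind = noise_model.get("kind", "gaussian_sqrt")
    if kind == "gaussian_sqrt":
        sd = noise_model.get("scale", 1.0) * np.sqrt(np.maximum(mean, 0.0))
        if np.any(np.asarray(sd) < 0):
            raise AnalysisValidationError("noise sd must be nonnegative")
        return np.maximum(mean + rng.normal(0.0, 1.0, mean.shape) * sd, 0.0)
    if kind == "gaussian_frac":
        sd = noise_model.get("frac", 0.1) * np.maximum(mean, 0.0)
        return np.maximum(mean + rng.normal(0.0, 1.0, mean.shape) * sd, 0.0)
    if kind == "poisson":
        if np.any(mean < 0):
            raise AnalysisValidationError("Poisson noise needs nonnegative means")
        return rng.poisson(mean).astype(float)
    if kind == "none":
        return mean.copy()
    raise AnalysisValidationError(f"unknown noise model {kind!r}")


def _layer_depth_range(layer):
    return {
        "L2/3": (0.05, 0.33),
        "L4": (0.37, 0.56),
        "L5": (0.60, 0.74),
        "L6": (0.78, 0.97),
    }[layer]


def simulate_probe(
    truth: GroundTruth,
    n_input_sites: int = 8,
    n_output_sites: int = 8,
    seed: int = 0,
    with_psth: bool = True,
    n_unresponsive_sites: int = 0,
) -> SyntheticProbeDataset:
    """Simulate one probe placement from a ground truth.

    Input sites are split between L4 and L6, output sites between L2/3 and
    L5.  Input-site mean tuning follows the two-lobe von Mises curve with a
    small per-site jitter of the preferred direction; output-site means are
    the shared f(w(S)·population input mean).  Trial rates add the
    configured noise; PSTHs rise logistically with half-max at the layer's
    latency.  ``n_unresponsive_sites`` plants flat (blank-like) sites that
    SNR screening should reject.
    """
    if n_input_sites < 1 or n_output_sites < 1:
        raise AnalysisValidationError("need at least one site per group")
    rng = np.random.default_rng(seed)
    cfg = truth.config
    n_dir = len(truth.directions)
    n_cond = n_dir + 1
    n_reps = truth.n_reps
    bf = truth.blank_fraction
    n_blank = max(1, int(round(bf / (1.0 - bf) * n_dir * n_reps))) if bf > 0 else 1
    max_rep = max(n_reps, n_blank)

    # ---- site layout -----------------------------------------------------
    layers = []
    for i in range(n_output_sites):
        layers.append("L2/3" if i < (n_output_sites + 1) // 2 else "L5")
    for i in range(n_input_sites):
        layers.append("L4" if i < (n_input_sites + 1) // 2 else "L6")
    for _ in range(n_unresponsive_sites):
        layers.append("L4")
    depths = np.array(
        [rng.uniform(*_layer_depth_range(l)) for l in layers]
    )
    order = np.argsort(depths, kind="stable")
    layers = [layers[i] for i in order]
    depths = depths[order]
    n_sites = len(layers)
    kind = np.array(
        ["output" if l in ("L2/3", "L5") else "input" for l in layers]
    )
    responsive = np.ones(n_sites, dtype=bool)
    # mark the planted unresponsive sites (they were appended last pre-sort)
    unresp_ids = set(range(n_output_sites + n_input_sites,
                           n_output_sites + n_input_sites + n_unresponsive_sites))
    responsive = np.array([i not in unresp_ids for i in order])

    # ---- per-site mean tuning -------------------------------------------
    alpha, beta, r0 = cfg["alpha"], cfg["beta"], cfg["r0"]
    jitter = cfg.get("theta_jitter_deg", 5.0)
    input_tuning = []
    means = np.zeros((n_sites, n_cond))
    for s in range(n_sites):
        if not responsive[s]:
            means[s] = r0  # flat: indistinguishable from blank
            continue
        if kind[s] == "input":
            tp = (truth.theta_pref + rng.normal(0.0, jitter)) % 360.0
            site = {
                "theta_pref": tp,
                "theta_null": (tp + 180.0) % 360.0,
                "sigma1": cfg["sigma1"],
                "sigma2": cfg["sigma2"],
                "alpha": alpha * rng.uniform(0.9, 1.1),
                "beta": beta * rng.uniform(0.9, 1.1),
                "r0": r0,
            }
            input_tuning.append(site)
            means[s, :-1] = von_mises_direction(
                truth.directions, site["theta_pref"], site["sigma1"],
                site["sigma2"], site["alpha"], site["beta"], site["r0"],
            )
            means[s, -1] = site["r0"]
    truth.input_tuning = input_tuning
    # output means come from the realized population input mean, so the
    # invariant "output mean = f(w(S)·input-layer mean)" holds exactly even
    # with per-site amplitude jitter
    input_rows = (kind == "input") & responsive
    if not input_rows.any():
        raise AnalysisValidationError("no responsive input site")
    pop_input = means[input_rows].mean(axis=0)
    means[(kind == "output") & responsive] = apply_nonlinearity(
        truth.gain_curve * pop_input, truth.nonlinearity
    )

    # ---- trial rates -----------------------------------------------------
    # Input-site trials are means plus noise.  By default output trials are
    # coupled to the input: the output at repetition i is the forward pass
    # f(w(S) · realized input-layer average at rep i) plus output noise,
    # mirroring the repetition pairing of the transmission model.  With
    # coupling off, output trials are drawn around the noise-free mean.
    n_trials = np.array([n_reps] * n_dir + [n_blank])
    rates = np.full((n_sites, n_cond, max_rep), np.nan)
    coupled = bool(cfg.get("coupled_trials", True))
    out_scale = float(cfg.get("output_noise_scale", 1.0))
    out_noise = dict(truth.noise_model)
    if out_noise.get("kind") == "gaussian_sqrt":
        out_noise["scale"] = out_noise.get("scale", 1.0) * out_scale
    elif out_noise.get("kind") == "gaussian_frac":
        out_noise["frac"] = out_noise.get("frac", 0.1) * out_scale
    elif out_scale == 0.0:
        out_noise = {"kind": "none"}
    out_rows = (kind == "output") & responsive
    for c in range(n_cond):
        n = n_trials[c]
        in_block = _draw_noise(
            rng,
            np.repeat(means[input_rows, c : c + 1], n, axis=1),
            truth.noise_model,
        )
        rates[input_rows, c, :n] = in_block
        # unresponsive sites: blank-like trials everywhere
        flat_rows = ~responsive
        if flat_rows.any():
            rates[flat_rows, c, :n] = _draw_noise(
                rng, np.repeat(means[flat_rows, c : c + 1], n, axis=1),
                truth.noise_model,
            )
        if coupled:
            x = in_block.mean(axis=0)  # realized input-layer average per rep
            drive = apply_nonlinearity(
                truth.gain_curve[c] * x, truth.nonlinearity
            )
            target = np.repeat(drive[None, :], out_rows.sum(), axis=0)
        else:
            target = np.repeat(means[out_rows, c : c + 1], n, axis=1)
        rates[out_rows, c, :n] = _draw_noise(rng, target, out_noise)

    # ---- PSTHs -----------------------------------------------------------
    psth = None
    time_ms = None
    if with_psth:
        lo, hi = cfg["psth_window_ms"]
        bin_ms = cfg["bin_ms"]
        time_ms = np.arange(lo + bin_ms / 2.0, hi, bin_ms)
        rise = cfg["latency_rise_ms"]
        psth = np.full((n_sites, n_cond, max_rep, len(time_ms)), np.nan)
        base = r0
        psth_noise = 0.25 * truth.noise_model.get("scale", 1.0)
        for s in range(n_sites):
            lat = truth.latency_by_layer[layers[s]]
            onset = 1.0 / (1.0 + np.exp(-(time_ms - lat) / rise))
            for c in range(n_cond):
                n = n_trials[c]
                if c == n_cond - 1 or not responsive[s]:
                    mean_tc = np.full_like(time_ms, base)
                else:
                    mean_tc = base + (means[s, c] - base) * onset
                sd = psth_noise * np.sqrt(np.maximum(mean_tc, 0.0) + 1.0)
                psth[s, c, :n] = np.maximum(
                    mean_tc + rng.normal(0.0, 1.0, (n, len(time_ms))) * sd, 0.0
                )

    table = TrialResponseTable(
        probe_id=f"synthetic-{truth.seed}-{seed}",
        site_ids=[f"site{i:02d}" for i in range(n_sites)],
        relative_depth=depths,
        area_label="A17",
        directions=truth.directions,
        rates=rates,
        n_trials=n_trials,
        psth=psth,
        time_ms=time_ms,
        bin_ms=cfg["bin_ms"],
        stimulus_meta={"contrast": 0.9, "tf_hz": 2.0, "sf_cpd": 0.15,
                       "duration_s": 2.0},
    )
    return SyntheticProbeDataset(table=table, truth=truth, layer_labels=layers)


def simulate_coupled_timeseries(
    spec: dict, n_samples: int, seed: int = 0, burn_in: int = 200
) -> dict:
    """Simulate a stable VAR system with known directed couplings.

    ``spec`` holds ``coeffs`` (either (k, k) for a VAR(1) or (p, k, k)),
    optional ``noise_sd`` (scalar or per-channel), and optional ``labels``.
    Returns ``{"data": (n_samples, k) array, "labels": [...]}``.
    """
    coeffs = np.asarray(spec["coeffs"], dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p, k, k2 = coeffs.shape
    if k != k2:
        raise AnalysisValidationError("coefficient matrices must be square")
    comp = np.zeros((k * p, k * p))
    for l in range(p):
        comp[:k, l * k : (l + 1) * k] = coeffs[l]
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    if np.max(np.abs(np.linalg.eigvals(comp))) >= 1.0:
        raise AnalysisValidationError("unstable VAR coefficient matrix")
    noise_sd = np.broadcast_to(
        np.asarray(spec.get("noise_sd", 1.0), dtype=float), (k,)
    )
    labels = list(spec.get("labels", [f"ch{i}" for i in range(k)]))
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    x = np.zeros((total + p, k))
    eps = rng.normal(0.0, 1.0, (total + p, k)) * noise_sd
    for t in range(p, total + p):
        acc = eps[t].copy()
        for l in range(p):
            acc += coeffs[l] @ x[t - 1 - l]
        x[t] = acc
    return {"data": x[p + burn_in :], "labels": labels}
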