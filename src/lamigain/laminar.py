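"""Latency estimation, layer assignment, CSD, and probe perpendicularity QC.

Recording sites carry a relative cortical depth in [0, 1] (0 = border
between cortical surface and L2/3, 1 = border between L6 and white matter).
Four layers are delimited by three relative depths (defaults 0.35, 0.58,
0.76, top to bottom); L2/3 and L5 form the "output layers", L4 and L6 the
"input layers".  Boundary membership is lower-closed / upper-open.

Response latency is the first post-onset time at which the
baseline-subtracted response reaches half of its post-onset maximum, with
linear interpolation between bins.  The maximum is searched within a
configurable post-onset window (default 0-200 ms) to avoid rebound peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisValidationError, UndefinedStatisticError

__all__ = [
    "LAYERS",
    "LayerAssignmentConfig",
    "ProbeQC",
    "compute_latency",
    "assign_layers",
    "layer_of_depth",
    "group_of_layer",
    "compute_csd",
    "probe_qc",
    "running_median",
]

LAYERS = ("L2/3", "L4", "L5", "L6")
OUTPUT_LAYERS = frozenset({"L2/3", "L5"})


@dataclass(frozen=True)
class LayerAssignmentConfig:
    """Relative-depth boundaries between neighboring layers."""

    boundaries: Sequence[float] = (0.35, 0.58, 0.76)
    depth_zero_anchor: str = "border between cortical surface and L2/3"
    depth_one_anchor: str = "border between L6 and white matter"

    def __post_init__(self):
        b = tuple(self.boundaries)
        if len(b) != 3 or not (0.0 < b[0] < b[1] < b[2] < 1.0):
            raise AnalysisValidationError(
                "boundaries must be three increasing depths inside (0, 1)"
            )


@dataclass(frozen=True)
class ProbeQC:
    """Perpendicularity QC of one probe placement."""

    rf_center_dispersion: float
    orientation_consistency: float
    rf_list: tuple  # per-site (x, y, radius) in degrees of visual angle


def compute_latency(
    psth,
    time_ms,
    baseline_window: Sequence[float] = (-100.0, 0.0),
    search_window: Sequence[float] = (0.0, 200.0),
) -> float:
    """Half-maximum response latency of a trial-averaged time course, ms.

    The pre-stimulus mean over ``baseline_window`` is subtracted; the
    latency is the first post-onset time where the response reaches half of
    its maximum within ``search_window``, linearly interpolated.
    """
    r = np.asarray(psth, dtype=float)
    t = np.asarray(time_ms, dtype=float)
    if r.shape != t.shape or r.ndim != 1:
        raise AnalysisValidationError("psth and time axes must align")
    base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not base_mask.any():
        raise AnalysisValidationError("baseline window outside recorded span")
    x = r - r[base_mask].mean()
    post = (t >= search_window[0]) & (t <= search_window[1])
    if not post.any():
        raise AnalysisValidationError("search window outside recorded span")
    peak = x[post].max()
    if peak <= 0:
        raise UndefinedStatisticError("post-onset maximum not above baseline")
    half = peak / 2.0
    tp, xp = t[post], x[post]
    above = np.nonzero(xp >= half)[0]
    k = above[0]
    if k == 0:
        return float(tp[0])
    # linear interpolation between the straddling bins
    t0, t1 = tp[k - 1], tp[k]
    x0, x1 = xp[k - 1], xp[k]
    return float(t0 + (half - x0) / (x1 - x0) * (t1 - t0))


def layer_of_depth(depth: float, config: LayerAssignmentConfig = LayerAssignmentConfig()) -> str:
    """Layer of one relative depth; intervals are [b, next_b)."""
    if not 0.0 <= depth <= 1.0:
        raise AnalysisValidationError(f"relative depth {depth} outside [0, 1]")
    b1, b2, b3 = config.boundaries
    if depth < b1:
        return "L2/3"
    if depth < b2:
        return "L4"
    if depth < b3:
        return "L5"
    return "L6"


def group_of_layer(layer: str) -> str:
    """'output' for L2/3 and L5, 'input' for L4 and L6."""
    if layer not in LAYERS:
        raise AnalysisValidationError(f"unknown layer {layer!r}")
    return "output" if layer in OUTPUT_LAYERS else "input"


def assign_layers(profiles, config: LayerAssignmentConfig = LayerAssignmentConfig()):
    """Assign layer and input/output group to each site profile in place.

    ``profiles`` is a sequence of objects with ``relative_depth``; each is
    given ``layer`` and ``group`` attributes.  Returns the same list.
    """
    for p in profiles:
        p.layer = layer_of_depth(p.relative_depth, config)
        p.group = group_of_layer(p.layer)
    return list(profiles)


def compute_csd(lfp, spacing_um: float) -> np.ndarray:
    """Current source density as the negative second spatial difference.

    CSD(d, t) = −(LFP(d−1, t) − 2·LFP(d, t) + LFP(d+1, t)) / spacing².
    Edge channels are dropped: output has 2 fewer depth rows.
    """
    x = np.asarray(lfp, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise AnalysisValidationError("LFP must be (depth >= 3, time)")
    if spacing_um <= 0:
        raise AnalysisValidationError("spacing must be positive")
    return -(x[:-2] - 2.0 * x[1:-1] + x[2:]) / spacing_um**2


def probe_qc(rf_list, preferred_orientations) -> ProbeQC:
    """Perpendicularity QC from receptive fields and preferred orientations.

    RF center dispersion is the mean Euclidean distance of RF centers from
    their mean, divided by twice the geometric mean of the RF radii (a
    population-averaged RF diameter).  Orientation consistency is the
    modulus of the mean unit phasor at the doubled orientation angle; it is
    1 iff all preferred orientations agree modulo 180°.
    """
    rf = [(float(x), float(y), float(s)) for x, y, s in rf_list]
    ori = np.asarray(preferred_orientations, dtype=float)
    if len(rf) < 2 or len(ori) != len(rf):
        raise AnalysisValidationError("need >= 2 sites with RF fits and orientations")
    radii = np.array([s for _, _, s in rf])
    if np.any(radii <= 0):
        raise AnalysisValidationError("RF radii must be positive")
    centers = np.array([(x, y) for x, y, _ in rf])
    mean_center = centers.mean(axis=0)
    spread = float(np.mean(np.linalg.norm(centers - mean_center, axis=1)))
    diameter = 2.0 * float(np.exp(np.mean(np.log(radii))))
    dispersion = spread / diameter

    phasors = np.exp(2j * np.deg2rad(ori))
    consistency = float(abs(phasors.mean()))
    return ProbeQC(
        rf_center_dispersion=dispersion,
        orientation_consistency=consistency,
        rf_list=tuple(rf),
    )


def running_median(
    depths,
    values,
    window: int = 7,
    n_boot: int = 1000,
    seed: Optional[int] = None,
):
    """Centered running median of ``values`` along ascending depth.

    Returns (sorted depths, running medians, bootstrap SEM of each median).
    The window covers ``window`` neighboring sites, truncated at the ends.
    """
    d = np.asarray(depths, dtype=float)
    v = np.asarray(values, dtype=float)
    order = np.argsort(d, kind="stable")
    d, v = d[order], v[order]
    half = window // 2
    rng = np.random.default_rng(seed)
    med = np.empty(len(v))
    sem = np.empty(len(v))
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        chunk = v[lo:hi]
        med[i] = np.median(chunk)
        boots = np.median(
            rng.choice(chunk, size=(n_boot, len(chunk)), replace=True), axis=1
        )
        sem[i] = boots.std(ddof=1)
    return d, med, sem
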