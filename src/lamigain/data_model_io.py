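"""Trial-resolved laminar response tables, on-disk formats, and SNR screening.

The central container is :class:`TrialResponseTable`: one probe placement's
trial-by-condition-by-site responses to drifting gratings plus a blank
(uniform gray) condition.  Stimulus directions are degrees in [0, 360),
counterclockwise; the blank condition is a reserved token, never an angle.
Rates are spikes/s.  Peristimulus time courses (PSTHs), when present, share
one bin width (default 2 ms) and one time axis with stimulus onset at 0 ms.

Because blank trials are interleaved at a different rate (~10 % of trials)
than each grating direction, per-condition trial counts differ; trial axes
are therefore NaN-padded to the maximum repetition count and accompanied by
an explicit ``n_trials`` vector.

Site-level quality control follows the response-variance criterion: the SNR
of a site is the maximum over directions of the variance of the
trial-averaged PSTH in the 0-200 ms post-onset window, divided by the same
variance under the blank condition; only sites with SNR strictly greater
than 8 enter further analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, UndefinedStatisticError

BLANK = "blank"
SNR_THRESHOLD = 8.0
SNR_WINDOW_MS = (0.0, 200.0)

__all__ = [
    "layer_averaged_rates",
    "BLANK",
    "SNR_THRESHOLD",
    "SNR_WINDOW_MS",
    "TrialResponseTable",
    "SnrResult",
    "SiteProfile",
    "read_trial_table",
    "write_trial_table",
    "compute_snr",
    "screen_sites",
]


@dataclass
class TrialResponseTable:
    """Responses of one probe placement.

    Parameters
    ----------
    probe_id : str
        Identifier of the probe placement.
    site_ids : list of str
        One identifier per recording site.
    relative_depth : ndarray, shape (n_sites,)
        Relative cortical depth in [0, 1] (0 = pia/L2-3 border, 1 = white
        matter border).
    area_label : str
        Cortical area, e.g. ``"A17"`` or ``"A18"``.
    directions : ndarray, shape (n_gratings,)
        Grating drift directions in degrees, distinct modulo 360.
    rates : ndarray, shape (n_sites, n_conditions, max_trials)
        Time-averaged rates (spikes/s); the last condition is the blank.
        Missing repetitions are NaN.
    n_trials : ndarray of int, shape (n_conditions,)
        Valid repetitions per condition.
    psth : ndarray or None, shape (n_sites, n_conditions, max_trials, n_time)
        Optional single-trial rate time courses.
    time_ms : ndarray or None, shape (n_time,)
        Bin centers in ms relative to stimulus onset.
    bin_ms : float
        PSTH bin width in ms.
    stimulus_meta : dict
        Contrast, spatial/temporal frequency, duration - for record only.
    """

    probe_id: str
    site_ids: list
    relative_depth: np.ndarray
    area_label: str
    directions: np.ndarray
    rates: np.ndarray
    n_trials: np.ndarray
    psth: Optional[np.ndarray] = None
    time_ms: Optional[np.ndarray] = None
    bin_ms: float = 2.0
    stimulus_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.relative_depth = np.asarray(self.relative_depth, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.validate()

    # ---- derived layout -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_gratings(self) -> int:
        return len(self.directions)

    @property
    def n_conditions(self) -> int:
        return self.n_gratings + 1

    @property
    def blank_index(self) -> int:
        return self.n_conditions - 1

    @property
    def condition_labels(self) -> list:
        return [f"{d:g}" for d in self.directions] + [BLANK]

    def site_index(self, site_id) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise KeyError(f"unknown site id {site_id!r}") from None

    def validate(self) -> None:
        if self.rates.ndim != 3:
            raise IntegrityError("rates must be (site, condition, trial)")
        n_sites, n_cond, max_rep = self.rates.shape
        if n_sites != len(self.site_ids):
            raise IntegrityError("site_ids length does not match rates")
        if len(self.relative_depth) != n_sites:
            raise IntegrityError("relative_depth length does not match sites")
        if n_cond != self.n_gratings + 1:
            raise IntegrityError(
                "rates condition axis must hold all directions plus one blank"
            )
        if n_cond < 2:
            raise IntegrityError("blank condition missing")
        wrapped = np.sort(np.mod(self.directions, 360.0))
        if len(wrapped) != len(np.unique(wrapped)):
            raise IntegrityError("directions must be distinct modulo 360")
        if len(self.n_trials) != n_cond:
            raise IntegrityError("n_trials length does not match conditions")
        if np.any(self.n_trials < 1):
            raise IntegrityError("every condition needs at least one trial")
        if np.any(self.n_trials > max_rep):
            raise IntegrityError("n_trials exceeds trial axis length")
        for c, n in enumerate(self.n_trials):
            block = self.rates[:, c, :n]
            if np.any(~np.isfinite(block)):
                raise IntegrityError(
                    f"condition {self.condition_labels[c]} has non-finite "
                    "rates within its declared trial count"
                )
        if np.any((self.relative_depth < 0) | (self.relative_depth > 1)):
            raise IntegrityError("relative_depth must lie in [0, 1]")
        if self.psth is not None:
            self.psth = np.asarray(self.psth, dtype=float)
            if self.psth.shape[:3] != self.rates.shape:
                raise IntegrityError("psth leading axes must match rates")
            if self.time_ms is None:
                raise IntegrityError("psth present but time_ms missing")
            self.time_ms = np.asarray(self.time_ms, dtype=float)
            if self.psth.shape[3] != len(self.time_ms):
                raise IntegrityError("psth time axis does not match time_ms")

    # ---- convenience ----------------------------------------------------
    def mean_rates(self) -> np.ndarray:
        """Trial-averaged rates, shape (n_sites, n_conditions)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.rates, axis=2)

    def trial_psth(self, site: int, cond: int) -> np.ndarray:
        """Trial-averaged PSTH of one (site, condition), shape (n_time,)."""
        if self.psth is None:
            raise IntegrityError("table carries no PSTHs")
        n = self.n_trials[cond]
        return np.nanmean(self.psth[site, cond, :n], axis=0)

    def copy(self) -> "TrialResponseTable":
        return replace(
            self,
            rates=self.rates.copy(),
            psth=None if self.psth is None else self.psth.copy(),
        )


@dataclass(frozen=True)
class SnrResult:
    """Response-variance SNR of one recording site."""

    snr: float
    var_by_condition: np.ndarray  # per-direction variances, gratings only
    var_blank: float
    passes: bool


@dataclass
class SiteProfile:
    """Per-site derived quantities accumulated through the pipeline."""

    site_id: object
    relative_depth: float
    snr: Optional[SnrResult] = None
    layer: Optional[str] = None
    group: Optional[str] = None  # "input" | "output"
    latency_ms: Optional[float] = None
    direction_fit: Optional[object] = None
    orientation_fit: Optional[object] = None
    f1f0: Optional[float] = None


def layer_averaged_rates(table: TrialResponseTable, site_indices) -> np.ndarray:
    """Rates averaged across the given sites, (n_conditions, max_trials).

    NaN padding beyond each condition's trial count is preserved.
    """
    idx = np.asarray(site_indices, dtype=int)
    if idx.size == 0:
        raise IntegrityError("no sites to average")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(table.rates[idx], axis=0)


# --------------------------------------------------------------------------
# SNR screening
# --------------------------------------------------------------------------

def compute_snr(
    table: TrialResponseTable,
    site,
    window_ms: Sequence[float] = SNR_WINDOW_MS,
    threshold: float = SNR_THRESHOLD,
) -> SnrResult:
    """SNR of one site: max over directions of Var(PSTH) / Var(blank PSTH).

    Variances are taken over time bins of the trial-averaged PSTH within
    ``window_ms`` (default 0-200 ms post onset), with ddof=1; the ddof
    choice cancels in the ratio.

    Raises
    ------
    UndefinedStatisticError
        If the blank-condition variance is zero.
    """
    if table.psth is None:
        raise IntegrityError("SNR needs PSTHs; table carries rates only")
    s = table.site_index(site) if not isinstance(site, (int, np.integer)) else int(site)
    lo, hi = float(window_ms[0]), float(window_ms[1])
    t = table.time_ms
    if lo < t[0] - table.bin_ms / 2 or hi > t[-1] + table.bin_ms / 2:
        raise IntegrityError("SNR window outside the recorded span")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise IntegrityError("SNR window spans fewer than 2 bins")

    var = np.empty(table.n_conditions)
    for c in range(table.n_conditions):
        var[c] = np.var(table.trial_psth(s, c)[mask], ddof=1)
    var_blank = var[table.blank_index]
    var_dir = var[: table.n_gratings]
    if var_blank == 0:
        raise UndefinedStatisticError(
            f"site {table.site_ids[s]!r}: blank-condition variance is zero"
        )
    snr = float(np.max(var_dir) / var_blank)
    return SnrResult(
        snr=snr,
        var_by_condition=var_dir,
        var_blank=float(var_blank),
        passes=snr > threshold,
    )


def screen_sites(
    table: TrialResponseTable,
    threshold: float = SNR_THRESHOLD,
    window_ms: Sequence[float] = SNR_WINDOW_MS,
) -> list:
    """Keep sites with SNR strictly above ``threshold``.

    Returns :class:`SiteProfile` stubs ordered by ascending relative depth.
    Sites with undefined SNR (zero blank variance) are excluded.  An empty
    survivor set is returned as an empty list, not raised.
    """
    survivors = []
    for s in range(table.n_sites):
        try:
            res = compute_snr(table, s, window_ms=window_ms, threshold=threshold)
        except UndefinedStatisticError:
            continue
        if res.snr > threshold:
            survivors.append(
                SiteProfile(
                    site_id=table.site_ids[s],
                    relative_depth=float(table.relative_depth[s]),
                    snr=res,
                )
            )
    survivors.sort(key=lambda p: p.relative_depth)
    return survivors


# --------------------------------------------------------------------------
# On-disk formats
# --------------------------------------------------------------------------

_CSV_COLUMNS = ["probe_id", "site_id", "relative_depth", "condition", "trial", "rate"]


def write_trial_table(table: TrialResponseTable, path, dialect: str = "hdf5") -> None:
    """Write a table to disk.

    ``hdf5`` stores rates and PSTHs; ``csv`` is a long-format text table of
    rates only (PSTHs are unavailable in the CSV dialect).
    """
    if dialect == "hdf5":
        _write_hdf5(table, path)
    elif dialect == "csv":
        _write_csv(table, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_trial_table(path, dialect: str = "hdf5") -> TrialResponseTable:
    """Read and validate a table written by :func:`write_trial_table`."""
    if dialect == "hdf5":
        return _read_hdf5(path)
    if dialect == "csv":
        return _read_csv(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def _write_hdf5(table: TrialResponseTable, path) -> None:
    with h5py.File(path, "w") as f:
        meta = {
            "probe_id": table.probe_id,
            "area_label": table.area_label,
            "bin_ms": table.bin_ms,
            "stimulus_meta": table.stimulus_meta,
        }
        f.attrs["meta"] = json.dumps(meta)
        sites = f.create_group("sites")
        sites.create_dataset(
            "id", data=np.array([str(s) for s in table.site_ids], dtype="S")
        )
        sites.create_dataset("depth", data=table.relative_depth)
        f.create_dataset(
            "conditions",
            data=np.array(table.condition_labels, dtype="S"),
        )
        f.create_dataset("rates", data=table.rates)
        f.create_dataset("n_trials", data=table.n_trials)
        if table.psth is not None:
            f.create_dataset("psth", data=table.psth)
            f.create_dataset("time_ms", data=table.time_ms)


def _read_hdf5(path) -> TrialResponseTable:
    with h5py.File(path, "r") as f:
        for key in ("sites", "conditions", "rates", "n_trials"):
            if key not in f:
                raise FormatError(f"missing dataset /{key}")
        if "meta" not in f.attrs:
            raise FormatError("missing attribute 'meta'")
        meta = json.loads(f.attrs["meta"])
        labels = [c.decode() for c in f["conditions"][()]]
        if labels[-1] != BLANK:
            raise IntegrityError("blank condition missing or not last")
        directions = np.array([float(c) for c in labels[:-1]])
        psth = f["psth"][()] if "psth" in f else None
        time_ms = f["time_ms"][()] if "time_ms" in f else None
        return TrialResponseTable(
            probe_id=meta["probe_id"],
            site_ids=[s.decode() for s in f["sites/id"][()]],
            relative_depth=f["sites/depth"][()],
            area_label=meta.get("area_label", ""),
            directions=directions,
            rates=f["rates"][()],
            n_trials=f["n_trials"][()],
            psth=psth,
            time_ms=time_ms,
            bin_ms=float(meta.get("bin_ms", 2.0)),
            stimulus_meta=meta.get("stimulus_meta", {}),
        )


def _write_csv(table: TrialResponseTable, path) -> None:
    rows = []
    labels = table.condition_labels
    for s, sid in enumerate(table.site_ids):
        for c, lab in enumerate(labels):
            for i in range(table.n_trials[c]):
                rows.append(
                    (
                        table.probe_id,
                        str(sid),
                        table.relative_depth[s],
                        lab,
                        i,
                        table.rates[s, c, i],
                    )
                )
    # %.17g renders doubles exactly, so the CSV dialect round-trips bit-exact
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def _read_csv(path) -> TrialResponseTable:
    df = pd.read_csv(
        path,
        dtype={"condition": str, "site_id": str},
        float_precision="round_trip",
    )
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"CSV missing columns: {sorted(missing)}")
    if df.duplicated(subset=["site_id", "condition", "trial"]).any():
        raise IntegrityError("duplicate (site, condition, trial) keys")
    if not (df["condition"] == BLANK).any():
        raise IntegrityError("blank condition missing")
    probe_ids = df["probe_id"].unique()
    if len(probe_ids) != 1:
        raise IntegrityError("CSV must contain exactly one probe placement")

    site_ids = list(df["site_id"].drop_duplicates())
    depth = df.drop_duplicates("site_id").set_index("site_id")["relative_depth"]
    # first-appearance order preserves the writer's condition order
    grating_labels = [c for c in df["condition"].drop_duplicates() if c != BLANK]
    labels = grating_labels + [BLANK]
    n_trials = np.array(
        [df[df["condition"] == lab]["trial"].nunique() for lab in labels]
    )
    rates = np.full((len(site_ids), len(labels), int(n_trials.max())), np.nan)
    s_idx = {s: i for i, s in enumerate(site_ids)}
    c_idx = {c: i for i, c in enumerate(labels)}
    for row in df.itertuples(index=False):
        rates[s_idx[row.site_id], c_idx[row.condition], int(row.trial)] = row.rate
    return TrialResponseTable(
        probe_id=str(probe_ids[0]),
        site_ids=site_ids,
        relative_depth=depth.loc[site_ids].to_numpy(),
        area_label="",
        directions=np.array([float(c) for c in grating_labels]),
        rates=rates,
        n_trials=n_trials,
    )
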