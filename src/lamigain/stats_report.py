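"""Interlaminar statistical battery and the end-to-end pipeline.

Interlaminar comparisons use one value per probe placement: the median
over recording sites within the input layers and within the output layers.
Paired groups are compared with the Wilcoxon signed-rank test, independent
groups with the Wilcoxon rank-sum test, both two-sided; proportions with a
chi-square test on the 2×2 contingency table; associations with the
Spearman rank correlation; deviations of a group median from a reference
value with an exact two-sided sign test.  Bonferroni correction is applied
only where families of comparisons arise (GC condition contrasts).
The SEM of a median is estimated by a seeded bootstrap (1000 resamples).

``run_pipeline`` chains the full analysis on synthetic probes:
screening → tuning → layer assignment → gain models → GC → statistics,
writing CSV/JSON outputs and a human-readable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import gc_connectivity as gc
from . import laminar, tuning
from .data_model_io import layer_averaged_rates, screen_sites
from .errors import AnalysisValidationError, UndefinedStatisticError
from .gain_models import (
    contribution_decomposition,
    fit_gain_model,
    gain_dsi,
    response_ratio_tuning,
)
from .synthetic_data import (
    make_ground_truth,
    simulate_coupled_timeseries,
    simulate_probe,
)

__all__ = [
    "ComparisonResult",
    "interlaminar_compare",
    "proportion_compare",
    "spearman_assoc",
    "sign_test",
    "median_sem",
    "bonferroni",
    "run_pipeline",
    "PipelineConfig",
]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    n: int
    effect_summary: dict = field(default_factory=dict)
    corrected_p: Optional[float] = None
    warnings: list = field(default_factory=list)


def median_sem(values, n_boot: int = 1000, seed: Optional[int] = 0) -> float:
    """Bootstrap SEM of the median (1000 seeded resamples)."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    boots = np.median(rng.choice(v, size=(n_boot, len(v)), replace=True), axis=1)
    return float(boots.std(ddof=1))


def bonferroni(p: float, n_comparisons: int) -> float:
    """Multiply p by the number of comparisons, capped at 1."""
    return min(1.0, p * n_comparisons)


def interlaminar_compare(a, b, paired: bool = True, seed: int = 0) -> ComparisonResult:
    """Compare two groups of per-probe medians.

    Paired groups (same probes) use the Wilcoxon signed-rank test,
    independent groups the Wilcoxon rank-sum test; both two-sided.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    warnings = []
    if paired and len(x) != len(y):
        raise AnalysisValidationError("paired comparison needs aligned groups")
    if min(len(x), len(y)) < 5:
        warnings.append("low power: fewer than 5 observations per group")
    if paired:
        d = x - y
        if np.allclose(d, 0.0):
            res_stat, res_p = 0.0, 1.0
            warnings.append("all paired differences are zero")
        else:
            r = stats.wilcoxon(x, y)
            res_stat, res_p = float(r.statistic), float(r.pvalue)
        test = "wilcoxon-signed-rank"
        n = len(x)
    else:
        r = stats.ranksums(x, y)
        res_stat, res_p = float(r.statistic), float(r.pvalue)
        test = "wilcoxon-rank-sum"
        n = len(x) + len(y)
    return ComparisonResult(
        test=test,
        statistic=res_stat,
        p_value=res_p,
        n=n,
        effect_summary={
            "median_a": float(np.median(x)),
            "sem_a": median_sem(x, seed=seed),
            "median_b": float(np.median(y)),
            "sem_b": median_sem(y, seed=seed + 1),
        },
        warnings=warnings,
    )


def proportion_compare(k_a: int, n_a: int, k_b: int, n_b: int) -> ComparisonResult:
    """Chi-square test comparing two proportions (2×2 contingency table)."""
    if n_a == 0 or n_b == 0:
        raise AnalysisValidationError("group sizes must be positive")
    if k_a > n_a or k_b > n_b:
        raise AnalysisValidationError("k must not exceed n")
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # degenerate margins: identical proportions of 0 or 1
        return ComparisonResult("chi-square", 0.0, 1.0, n_a + n_b)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonResult(
        test="chi-square",
        statistic=float(chi2),
        p_value=float(p),
        n=n_a + n_b,
        effect_summary={"prop_a": k_a / n_a, "prop_b": k_b / n_b},
    )


def spearman_assoc(x, y) -> ComparisonResult:
    """Spearman rank correlation with two-sided p."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise AnalysisValidationError("need aligned vectors with n >= 5")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedStatisticError("constant input; correlation undefined")
    r = stats.spearmanr(a, b)
    return ComparisonResult(
        test="spearman",
        statistic=float(r.statistic),
        p_value=float(r.pvalue),
        n=len(a),
    )


def sign_test(values, null_value: float = 0.0) -> ComparisonResult:
    """Exact two-sided sign test of the median against ``null_value``.

    Exact binomial for n ≤ 100; normal approximation beyond.
    """
    v = np.asarray(values, dtype=float)
    signs = np.sign(v - null_value)
    signs = signs[signs != 0]
    n = len(signs)
    if n == 0:
        raise UndefinedStatisticError("all values tie the null; sign test undefined")
    k = int(np.sum(signs > 0))
    if n <= 100:
        p = float(stats.binomtest(k, n, 0.5).pvalue)
    else:
        z = (k - n / 2.0) / np.sqrt(n / 4.0)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        test="sign",
        statistic=float(k),
        p_value=p,
        n=n,
        effect_summary={"n_above": k, "n_below": n - k},
    )


# --------------------------------------------------------------------------
# End-to-end pipeline on synthetic data
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run specification for the synthetic end-to-end pipeline."""

    n_probes: int = 8
    truth_config: dict = field(default_factory=dict)
    n_input_sites: int = 6
    n_output_sites: int = 6
    snr_threshold: float = 8.0
    adj_r2_gate: float = 0.8
    family: str = "threshold_linear"
    fit_seeds: Sequence[int] = tuple(range(4))
    gc_n_samples: int = 3000
    gc_max_order: int = 8
    run_gc: bool = True


def _gc_condition_specs(strength_by_condition):
    """Layer-resolved VAR couplings whose planted strengths vary by
    condition: feedforward L4→L2/3 and L4→L5, recurrent L2/3→L5."""
    labels = ["L2/3", "L4", "L5"]
    specs = {}
    for cond, s in strength_by_condition.items():
        a = np.diag([0.4, 0.4, 0.4]).astype(float)
        a[0, 1] = s  # L4 -> L2/3
        a[2, 1] = 0.8 * s  # L4 -> L5
        a[2, 0] = 0.6 * s  # L2/3 -> L5
        specs[cond] = {"coeffs": a, "labels": labels, "noise_sd": 1.0}
    return specs


def run_pipeline(config: PipelineConfig, seed: int = 0, out_dir=None) -> dict:
    """Run screening → tuning → layers → gain models → GC → statistics.

    Returns a report bundle (dict); when ``out_dir`` is given, writes
    sites.csv, gainfits.json, gc.json and report.md there.  Fully seeded:
    identical (config, seed) pairs give identical outputs.
    """
    rng = np.random.default_rng(seed)
    report: Dict = {"seed": seed, "stages": {}, "probes": []}
    site_rows = []
    per_probe = []

    for pi in range(config.n_probes):
        truth = make_ground_truth(config.truth_config, seed=int(rng.integers(2**31)))
        ds = simulate_probe(
            truth,
            n_input_sites=config.n_input_sites,
            n_output_sites=config.n_output_sites,
            seed=int(rng.integers(2**31)),
        )
        table = ds.table
        survivors = screen_sites(table, threshold=config.snr_threshold)
        if not survivors:
            report["stages"].setdefault("screening", []).append(
                {"probe": table.probe_id, "status": "failed", "reason": "no site passed SNR"}
            )
            continue
        laminar.assign_layers(survivors)
        mean_rates = table.mean_rates()

        probe = {"probe_id": table.probe_id, "truth_gain_dsi": truth.gain_dsi}
        dsis, groups, prefs, lats = [], [], [], []
        for p in survivors:
            s = table.site_index(p.site_id)
            resp = mean_rates[s, :-1]
            fit = tuning.fit_direction_tuning(resp, table.directions)
            p.direction_fit = fit
            try:
                summ = tuning.compute_dsi(fit)
            except UndefinedStatisticError:
                continue
            p.latency_ms = laminar.compute_latency(
                table.trial_psth(s, int(np.argmax(resp))), table.time_ms
            )
            dsis.append(summ.dsi)
            groups.append(p.group)
            prefs.append(fit.theta_pref)
            lats.append(p.latency_ms)
            site_rows.append(
                {
                    "probe_id": table.probe_id,
                    "site_id": p.site_id,
                    "relative_depth": p.relative_depth,
                    "layer": p.layer,
                    "group": p.group,
                    "snr": p.snr.snr,
                    "theta_pref": fit.theta_pref,
                    "dsi": summ.dsi,
                    "latency_ms": p.latency_ms,
                }
            )
        groups = np.array(groups)
        dsis = np.array(dsis)
        lats = np.array(lats)
        if not ((groups == "input").any() and (groups == "output").any()):
            report["stages"].setdefault("tuning", []).append(
                {"probe": table.probe_id, "status": "failed",
                 "reason": "one laminar group empty after screening"}
            )
            continue
        probe["median_dsi_input"] = float(np.median(dsis[groups == "input"]))
        probe["median_dsi_output"] = float(np.median(dsis[groups == "output"]))
        probe["median_latency_input"] = float(np.median(lats[groups == "input"]))
        probe["median_latency_output"] = float(np.median(lats[groups == "output"]))

        # ---- gain models -------------------------------------------------
        in_sites = [
            table.site_index(p.site_id) for p in survivors if p.group == "input"
        ]
        out_sites = [
            table.site_index(p.site_id) for p in survivors if p.group == "output"
        ]
        in_rates = layer_averaged_rates(table, in_sites)
        out_rates = layer_averaged_rates(table, out_sites)
        fits = {}
        for model in ("I", "II"):
            fits[model] = fit_gain_model(
                in_rates,
                out_rates,
                model=model,
                family=config.family,
                directions=table.directions,
                seeds=config.fit_seeds,
            )
        probe["adj_r2_model1"] = fits["I"].adj_r2
        probe["adj_r2_model2"] = fits["II"].adj_r2
        probe["bic_model1"] = fits["I"].bic
        probe["bic_model2"] = fits["II"].bic
        probe["gain_dsi_model2"] = gain_dsi(fits["II"])
        probe["passes_gate"] = fits["II"].adj_r2 > config.adj_r2_gate

        # DSI of data and of model outputs, all via the same fitted-curve path
        pop_in = np.nanmean(in_rates, axis=1)
        pop_out = np.nanmean(out_rates, axis=1)

        def _curve_dsi(values):
            f = tuning.fit_direction_tuning(values[:-1], table.directions)
            return tuning.compute_dsi(f).dsi, f.theta_pref

        dsi_in_pop, pref_in = _curve_dsi(pop_in)
        dsi_out_pop, _ = _curve_dsi(pop_out)
        dsi_m1, _ = _curve_dsi(fits["I"].mean_fitted_by_condition())
        dsi_m2, _ = _curve_dsi(fits["II"].mean_fitted_by_condition())
        probe.update(
            dsi_input_pop=dsi_in_pop,
            dsi_output_pop=dsi_out_pop,
            dsi_model1=dsi_m1,
            dsi_model2=dsi_m2,
        )
        try:
            cn, cg = contribution_decomposition(dsi_in_pop, dsi_out_pop, dsi_m1, dsi_m2)
            probe["contrib_nonlin"] = cn
            probe["contrib_gain"] = cg
        except UndefinedStatisticError:
            pass

        # ---- response ratio tuning --------------------------------------
        rr = response_ratio_tuning(pop_in, pop_out, table.directions, pref_in)
        probe["ratio_pref"] = rr.ratio_pref
        probe["ratio_null"] = rr.ratio_null
        probe["ratio_blank"] = rr.ratio_blank

        per_probe.append(probe)
        report["probes"].append(probe)

    if not per_probe:
        report["stages"]["pipeline"] = {"status": "failed", "reason": "no usable probe"}
        return report

    df = pd.DataFrame(per_probe)
    gated = df[df["passes_gate"]] if df["passes_gate"].any() else df

    comp = interlaminar_compare(
        df["median_dsi_output"], df["median_dsi_input"], paired=True, seed=seed
    )
    summary = {
        "n_probes": len(df),
        "n_gated": int(df["passes_gate"].sum()),
        "dsi_comparison": comp.__dict__,
        "median_dsi_output": float(df["median_dsi_output"].median()),
        "median_dsi_input": float(df["median_dsi_input"].median()),
        "median_latency_output": float(df["median_latency_output"].median()),
        "median_latency_input": float(df["median_latency_input"].median()),
        "mean_ratio_pref": float(gated["ratio_pref"].mean()),
        "mean_ratio_null": float(gated["ratio_null"].mean()),
        "mean_ratio_blank": float(gated["ratio_blank"].mean()),
        "mean_contrib_nonlin": float(gated["contrib_nonlin"].mean())
        if "contrib_nonlin" in gated
        else None,
        "mean_contrib_gain": float(gated["contrib_gain"].mean())
        if "contrib_gain" in gated
        else None,
        "mean_adj_r2_model2": float(gated["adj_r2_model2"].mean()),
    }
    report["summary"] = summary

    # ---- GC stage --------------------------------------------------------
    if config.run_gc:
        strengths = {"blank": 0.05, "null": 0.15, "pref": 0.30}
        norm_by_probe = []
        for _ in range(len(df)):
            specs = _gc_condition_specs(strengths)
            series = {
                c: simulate_coupled_timeseries(
                    s, config.gc_n_samples, seed=int(rng.integers(2**31))
                )["data"]
                for c, s in specs.items()
            }
            res = gc.gc_for_conditions(
                series, max_order=config.gc_max_order,
                channel_names=["L2/3", "L4", "L5"],
            )
            norm_by_probe.append(res.normalized_gc)
        norm = np.stack(norm_by_probe)  # (probes, cond, k, k)
        conds = list(strengths)
        k = norm.shape[2]
        contrasts = {}
        for ia, ib, name in ((2, 0, "pref_minus_blank"), (1, 0, "null_minus_blank"),
                             (2, 1, "pref_minus_null")):
            d, p = gc.contrast_conditions(
                norm[:, ia], norm[:, ib], n_comparisons=k * k
            )
            contrasts[name] = {"diff": d.tolist(), "p_corrected": p.tolist()}
        report["gc"] = {
            "conditions": conds,
            "channels": ["L2/3", "L4", "L5"],
            "contrasts": contrasts,
        }

    # ---- outputs ---------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(site_rows).to_csv(out / "sites.csv", index=False)
        df.to_csv(out / "probes.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        with open(out / "report.md", "w") as fh:
            fh.write(_render_report(report))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, ComparisonResult):
        return _jsonable(obj.__dict__)
    if hasattr(obj, "__dict__") and not isinstance(obj, type):
        return _jsonable(vars(obj))
    return obj


def _render_report(report: dict) -> str:
    s = report.get("summary", {})
    lines = [
        "# Laminar direction-selectivity pipeline report",
        "",
        f"Seed: {report['seed']}; probes analyzed: {s.get('n_probes', 0)} "
        f"({s.get('n_gated', 0)} pass the adjR2 gate)",
        "",
        "## Direction selectivity",
        f"- median DSI, output layers: {s.get('median_dsi_output', float('nan')):.4f}",
        f"- median DSI, input layers:  {s.get('median_dsi_input', float('nan')):.4f}",
        f"- interlaminar comparison p: {s.get('dsi_comparison', {}).get('p_value', float('nan')):.3g}",
        "",
        "## Latency",
        f"- median latency, output layers: {s.get('median_latency_output', float('nan')):.1f} ms",
        f"- median latency, input layers:  {s.get('median_latency_input', float('nan')):.1f} ms",
        "",
        "## Response ratio (output / input)",
        f"- preferred direction: {s.get('mean_ratio_pref', float('nan')):.3f}",
        f"- null direction:      {s.get('mean_ratio_null', float('nan')):.3f}",
        f"- blank:               {s.get('mean_ratio_blank', float('nan')):.3f}",
        "",
        "## Gain-model decomposition",
        f"- mean adjR2 of the tuned-gain model: {s.get('mean_adj_r2_model2', float('nan')):.4f}",
        f"- contribution of nonlinearity: {s.get('mean_contrib_nonlin') if s.get('mean_contrib_nonlin') is None else format(s['mean_contrib_nonlin'], '.3f')}",
        f"- contribution of tuned gain:   {s.get('mean_contrib_gain') if s.get('mean_contrib_gain') is None else format(s['mean_contrib_gain'], '.3f')}",
        "",
    ]
    if "gc" in report:
        lines += ["## Granger-causality contrasts",
                  "(mean difference of normalized GC; rows = target, cols = source)"]
        for name, c in report["gc"]["contrasts"].items():
            lines.append(f"- {name}: {np.array(c['diff']).round(3).tolist()}")
    return "\n".join(lines) + "\n"
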