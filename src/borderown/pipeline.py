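"""End-to-end analysis pipeline: simulate or ingest trials, estimate
effects, compare populations, quantify cross-scene consistency, and
estimate signal latencies; emit a single JSON report."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from borderown import consistency as cons
from borderown import effects as eff
from borderown import population as pop
from borderown import simulate as sim
from borderown import timecourse as tc
from borderown.io import PipelineConfig, read_trials


def fisher_consistency(c: float) -> float:
    """Fisher transform of a consistency index: arctanh(2c - 1), mapping
    the [0, 1] proportion onto the real line."""
    return float(np.arctanh(np.clip(2.0 * c - 1.0, -0.999999, 0.999999)))


def report_consistency_vs_latency(consistencies, latencies) -> tuple[float, float]:
    """Pearson correlation of Fisher-transformed consistency vs latency."""
    from scipy.stats import pearsonr

    z = [fisher_consistency(c) for c in consistencies]
    ok = np.isfinite(z) & np.isfinite(latencies)
    z = np.asarray(z)[ok]
    lat = np.asarray(latencies, dtype=float)[ok]
    if len(z) < 3:
        return float("nan"), float("nan")
    r, p = pearsonr(z, lat)
    return float(r), float(p)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and return the JSON-serializable report.

    Two runs with identical config produce identical reports: every random
    stage derives its stream from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if config.trials_path:
        cells = read_trials(config.trials_path)
        omis = None
    else:
        base = sim.preset_paper_calibrated(n_scenes=config.n_scenes)
        sampler = sim.default_population_sampler(base)
        cells = sim.simulate_population(config.n_cells, sampler, seed=rng)
        omis = [c.params.omi_value for c in cells]

    if omis is not None:
        cells = eff.filter_orientation_selective(cells, omis, config.min_omi)

    fits = [eff.fit_cell(c) for c in cells]
    estimates = [eff.extract_effects(f) for f in fits]

    report: dict = {"config": config.to_dict(), "n_cells": len(cells)}

    # population slopes
    slopes = {}
    for kind in ("full", "patch", "context"):
        pts = pop.scatter_points(estimates, kind=kind)
        fit = pop.bootstrap_slope_ci(pts, B=config.bootstrap_B, seed=rng)
        slopes[kind] = {
            "slope": fit.slope,
            "ci95": [fit.ci_low, fit.ci_high],
            "n_cells": fit.n_cells,
        }
    report["slopes"] = slopes

    prop, n_same, n_both = pop.preference_consistency(estimates, alpha=config.alpha)
    report["preference_consistency"] = {
        "proportion": prop,
        "n_consistent": n_same,
        "n_both_significant": n_both,
    }
    stat, p = pop.rotation_invariance_check(cells)
    report["rotation_invariance"] = {"wilcoxon_stat": stat, "p": p}

    # cross-scene consistency for cells significant in the full images
    sig_full = [
        (c, f)
        for c, f, e in zip(cells, fits, estimates)
        if e.p_full < config.alpha
    ]
    cons_results = []
    for cell, f in sig_full:
        res = cons.cell_consistency(
            f,
            n_surrogates=config.n_surrogates,
            seed=rng,
            n_cells_tested=max(len(sig_full), 1),
        )
        cons_results.append(res)
    report["consistency"] = [asdict(r) for r in cons_results]

    # population latencies on cells border-ownership selective in both tests
    selective = [
        c
        for c, e in zip(cells, estimates)
        if e.p_square < config.alpha and e.p_scene_bo < config.alpha
    ]
    lat_cells = selective if len(selective) >= 3 else cells
    table = tc.latency_table(lat_cells, B=config.bootstrap_B, seed=int(rng.integers(2**31)))
    report["latency_table"] = table.to_dict(orient="records")
    report["latency_cells"] = len(lat_cells)

    # consistency vs per-cell latency
    pref = tc.estimate_pref_signs(lat_cells)
    per_cell = {r.cell_id: r.corrected for r in cons_results}
    cvals, lvals = [], []
    for cell in lat_cells:
        if cell.cell_id not in per_cell:
            continue
        fit = tc.latency([cell], "bo_full", pref_signs=pref)
        if not fit.no_onset and np.isfinite(fit.latency_ms):
            cvals.append(per_cell[cell.cell_id])
            lvals.append(fit.latency_ms)
    r, p = report_consistency_vs_latency(cvals, lvals)
    report["consistency_vs_latency"] = {"pearson_r": r, "p": p, "n": len(cvals)}
    return report


def write_report(report: dict, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
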