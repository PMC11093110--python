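"""End-to-end orchestration: inputs to fits, comparisons and verdict.

``run_pipeline`` chains the stages — respirometry summaries, gill
aggregation, allometric fits, slope comparisons, mass correction,
Q10/FAS and growth summaries — and writes one CSV per stage plus a JSON
verdict report.  In simulate mode the inputs come from
:mod:`gillscale.synthetic_data`; in real-data mode from the CSV readers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from gillscale import allometry, organism_metrics
from gillscale.gill_morphometry import aggregate_gill_table
from gillscale.io import (
    RunConfig,
    read_fish,
    read_gills,
    traces_from_frame,
    write_table,
)
from gillscale.respirometry import (
    CycleConfig,
    OxygenTrace,
    analyze_rmr_trace,
    estimate_mmr,
    estimate_pcrit_llo,
    estimate_rmr,
    subtract_background,
)
from gillscale.synthetic_data import (
    CohortConfig,
    ScalingTruth,
    TraceConfig,
    generate_cohort,
    generate_gill_bins,
    generate_trace,
    ground_truth_sidecar,
)

log = logging.getLogger("gillscale")

TRAIT_COLUMNS = {
    "gsa_mm2": "GSA",
    "rmr_mg_o2_per_h": "RMR",
    "mmr_mg_o2_per_h": "MMR",
}
COMPONENT_COLUMNS = {
    "total_filament_length_mm": "L_fil",
    "lamellar_frequency_per_mm": "n_lam",
    "mean_lamellar_area_mm2": "A_lam",
}


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for json.dump."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _simulate_inputs(config: RunConfig) -> dict:
    sim = dict(config.simulate or {})
    cohort_kwargs = dict(sim.get("cohort", {}))
    cohort_kwargs.setdefault("seed", config.seed)
    cohort = CohortConfig(**cohort_kwargs)
    if "truth" in sim:
        truth = ScalingTruth(**sim["truth"])
    else:
        truth = ScalingTruth.preset(sim.get("scenario", "null"))
    gill_noise = float(sim.get("gill_noise_sd_log10", 0.05))
    trace_kwargs = dict(sim.get("trace", {}))
    fish = generate_cohort(cohort, truth)

    sampled = fish[fish["is_sampled"]]
    gills = pd.concat(
        [
            generate_gill_bins(
                row,
                noise_sd_log10=gill_noise,
                seed=cohort.seed,
                reference_hemibranch=config.reference_hemibranch,
            )
            for _, row in sampled.iterrows()
        ],
        ignore_index=True,
    )
    traces: dict[str, dict[str, OxygenTrace]] = {}
    cycles: dict[str, CycleConfig] = {}
    for _, row in sampled.iterrows():
        chamber = config.chamber_for(int(row["timepoint_days"]))
        tcfg = TraceConfig(
            system_volume_l=chamber.system_volume_l,
            flush_s=chamber.flush_s,
            wait_s=chamber.wait_s,
            measure_s=chamber.measure_s,
            seed=cohort.seed,
            **trace_kwargs,
        )
        fish_id = str(row["fish_id"])
        kinds = {"rmr": generate_trace(row, tcfg, "rmr")}
        kinds["mmr_chase"] = generate_trace(row, tcfg, "mmr_chase")
        if config.include_pcrit:
            kinds["pcrit_drawdown"] = generate_trace(row, tcfg, "pcrit_drawdown")
        traces[fish_id] = kinds
        cycles[fish_id] = CycleConfig(
            flush_s=tcfg.flush_s, wait_s=tcfg.wait_s, measure_s=tcfg.measure_s
        )
    return {
        "fish": fish,
        "gills": gills,
        "traces": traces,
        "cycles": cycles,
        "truth": ground_truth_sidecar(cohort, truth),
        "background": (
            float(trace_kwargs.get("background_rate_start", 0.0)),
            float(trace_kwargs.get("background_rate_end", 0.0)),
        ),
    }


def _load_inputs(config: RunConfig) -> dict:
    fish = read_fish(config.fish_csv)
    gills = read_gills(config.gills_csv) if config.gills_csv else None
    traces: dict[str, dict[str, OxygenTrace]] = {}
    cycles: dict[str, CycleConfig] = {}
    if config.traces_csv:
        meta = fish.copy()
        meta["system_volume_l"] = [
            config.chamber_for(int(t)).system_volume_l
            for t in meta["timepoint_days"]
        ]
        df = pd.read_csv(config.traces_csv)
        df.columns = [str(c).strip() for c in df.columns]
        if "kind" not in df.columns:
            df["kind"] = "rmr"
        for kind, sub in df.groupby("kind"):
            for trace in traces_from_frame(sub, meta):
                traces.setdefault(trace.fish_id, {})[str(kind)] = trace
        for _, row in fish.iterrows():
            chamber = config.chamber_for(int(row["timepoint_days"]))
            cycles[str(row["fish_id"])] = CycleConfig(
                flush_s=chamber.flush_s,
                wait_s=chamber.wait_s,
                measure_s=chamber.measure_s,
            )
    return {
        "fish": fish,
        "gills": gills,
        "traces": traces,
        "cycles": cycles,
        "truth": None,
        "background": (0.0, 0.0),
    }


def summarize_respirometry(
    traces: dict[str, dict[str, OxygenTrace]],
    cycles: dict[str, CycleConfig],
    config: RunConfig,
    background: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Per-fish RMR, MMR and P_crit from the raw traces."""
    rows = []
    for fish_id, kinds in traces.items():
        rmr_trace = kinds.get("rmr")
        if rmr_trace is None:
            continue
        estimates = analyze_rmr_trace(
            rmr_trace, cycles[fish_id], r2_threshold=config.r2_threshold
        )
        pre, post = background
        if pre or post:
            estimates = subtract_background(
                estimates, pre, post, rmr_trace.time_s[0], rmr_trace.time_s[-1]
            )
        n_total = len(estimates)
        n_accepted = sum(e.accepted for e in estimates)
        for e in estimates:
            if not e.accepted:
                log.info(
                    "%s: segment [%d, %d] rejected (R2=%.4f)",
                    fish_id,
                    e.window_start_s,
                    e.window_end_s,
                    e.r_squared,
                )
        rmr = estimate_rmr(estimates)
        mmr = pcrit = np.nan
        if "mmr_chase" in kinds:
            mmr, mmr_est = estimate_mmr(kinds["mmr_chase"], config.mmr_window_s)
            if config.background_correct_mmr and (pre or post):
                mmr = subtract_background(
                    [mmr_est],
                    pre,
                    post,
                    rmr_trace.time_s[0],
                    rmr_trace.time_s[-1],
                )[0].mo2_mg_o2_per_h
        if "pcrit_drawdown" in kinds:
            res = estimate_pcrit_llo(
                kinds["pcrit_drawdown"],
                rmr,
                bin_width_percent_sat=config.pcrit_bin_width,
            )
            pcrit = res.pcrit_percent_sat
        rows.append(
            {
                "fish_id": fish_id,
                "rmr_mg_o2_per_h": rmr,
                "mmr_mg_o2_per_h": mmr,
                "pcrit_percent_sat": pcrit,
                "n_slopes_total": n_total,
                "n_slopes_accepted": n_accepted,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns (and writes) the report bundle.

    Returns a dict with keys ``fish, morphometry, metabolic, analysis,
    fits, comparisons, growth, summary, report``.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _simulate_inputs(config) if config.simulate else _load_inputs(config)
    fish = inputs["fish"]

    morph = (
        aggregate_gill_table(inputs["gills"], config.reference_hemibranch)
        if inputs["gills"] is not None and len(inputs["gills"])
        else None
    )
    metabolic = summarize_respirometry(
        inputs["traces"], inputs["cycles"], config, inputs["background"]
    )

    # tidy per-fish analysis table at the lethal-sampling record
    sampled = fish[fish["is_sampled"]] if "is_sampled" in fish.columns else fish
    analysis = sampled[
        ["fish_id", "temperature_c", "timepoint_days", "mass_g"]
    ].copy()
    if morph is not None:
        analysis = analysis.merge(morph, on="fish_id", how="left")
        analysis = analysis.rename(columns={"gsa_mm2": "gsa_mm2"})
    if len(metabolic):
        analysis = analysis.merge(metabolic, on="fish_id", how="left")

    trait_cols = [
        c
        for c in list(TRAIT_COLUMNS) + list(COMPONENT_COLUMNS)
        if c in analysis.columns
    ]
    fits = allometry.fit_traits_by_temperature(analysis, trait_cols)
    fits_df = allometry.fits_to_frame(fits)

    by_key = {(f.trait, f.temperature_c): f for f in fits}
    comparisons, verdicts = [], {}
    temps = sorted(analysis["temperature_c"].unique())
    for temp in temps:
        gsa_fit = by_key.get(("gsa_mm2", temp))
        if gsa_fit is None:
            continue
        for mr_col, mr_name in (("rmr_mg_o2_per_h", "RMR"), ("mmr_mg_o2_per_h", "MMR")):
            mr_fit = by_key.get((mr_col, temp))
            if mr_fit is None:
                continue
            comp = allometry.scaling_difference(gsa_fit.b, mr_fit.b, mr_name)
            comparisons.append(
                {
                    "temperature_c": temp,
                    "mr_metric": mr_name,
                    "b_gsa": comp.b_gsa,
                    "b_mr": comp.b_mr,
                    "b_s": comp.b_s,
                    "consistent_with_gol_scenario2": comp.consistent_with_gol_scenario2,
                }
            )
    comparisons_df = pd.DataFrame(comparisons)
    if len(comparisons_df):
        all_nonneg = bool((comparisons_df["b_s"] >= 0).all())
        verdicts["b_s_all_nonnegative"] = all_nonneg
        verdicts["verdict"] = (
            "b_S >= 0 at both temperatures (inconsistent with GOL scenario 2)"
            if all_nonneg
            else "b_S < 0 detected (consistent with GOL scenario 2)"
        )

    # slope decomposition where gill components are available
    decomposition = []
    for temp in temps:
        fits_needed = [
            by_key.get((c, temp))
            for c in (
                "total_filament_length_mm",
                "lamellar_frequency_per_mm",
                "mean_lamellar_area_mm2",
            )
        ]
        gsa_fit = by_key.get(("gsa_mm2", temp))
        if all(f is not None for f in fits_needed) and gsa_fit is not None:
            d = allometry.decompose_gsa_slope(*fits_needed, fit_gsa=gsa_fit)
            d["temperature_c"] = temp
            d["b_gsa_direct"] = gsa_fit.b
            decomposition.append(d)

    # mass correction, FAS, Q10
    summary_rows = []
    if len(metabolic) and "rmr_mg_o2_per_h" in analysis.columns:
        mc_cfg = allometry.MassCorrectionConfig(config.reference_mass_g)
        corrected = analysis.dropna(subset=["rmr_mg_o2_per_h"]).copy()
        for col, trait in (("rmr_mg_o2_per_h", "rmr"), ("mmr_mg_o2_per_h", "mmr")):
            vals = []
            for _, row in corrected.iterrows():
                fit = by_key.get((col, row["temperature_c"]))
                if fit is None or not np.isfinite(row[col]) or row[col] <= 0:
                    vals.append(np.nan)
                else:
                    vals.append(
                        allometry.mass_correct(row[col], row["mass_g"], fit.b, mc_cfg)
                    )
            corrected[f"{trait}_mc"] = vals
        corrected["fas"] = corrected["mmr_mc"] / corrected["rmr_mc"]
        analysis = analysis.merge(
            corrected[["fish_id", "rmr_mc", "mmr_mc", "fas"]],
            on="fish_id",
            how="left",
        )
        means = (
            corrected.groupby(["temperature_c", "timepoint_days"])[
                ["rmr_mc", "mmr_mc", "fas"]
            ]
            .mean()
            .reset_index()
        )
        if len(temps) == 2:
            t1, t2 = temps
            for tp in sorted(means["timepoint_days"].unique()):
                r1 = means[(means["temperature_c"] == t1) & (means["timepoint_days"] == tp)]
                r2 = means[(means["temperature_c"] == t2) & (means["timepoint_days"] == tp)]
                if len(r1) and len(r2):
                    summary_rows.append(
                        {
                            "timepoint_days": tp,
                            "q10_rmr_mc": allometry.q10(
                                float(r1["rmr_mc"].iloc[0]),
                                float(r2["rmr_mc"].iloc[0]),
                                t1,
                                t2,
                            ),
                            "q10_mmr_mc": allometry.q10(
                                float(r1["mmr_mc"].iloc[0]),
                                float(r2["mmr_mc"].iloc[0]),
                                t1,
                                t2,
                            ),
                        }
                    )

    growth = organism_metrics.sgr_table(fish)
    growth_summary = organism_metrics.treatment_summary(fish)

    report = {
        "n_fish": int(fish["fish_id"].nunique()),
        "temperatures_c": [float(t) for t in temps],
        "comparisons": comparisons,
        "decomposition": decomposition,
        "q10": summary_rows,
        **verdicts,
    }
    if inputs["truth"] is not None:
        report["ground_truth"] = inputs["truth"]
    report = _jsonable(report)

    write_table(fish, outdir / "fish_records.csv")
    if morph is not None:
        write_table(morph, outdir / "gill_morphometry.csv")
    if len(metabolic):
        write_table(metabolic, outdir / "metabolic_summary.csv")
    write_table(analysis, outdir / "analysis_table.csv")
    write_table(fits_df, outdir / "allometric_fits.csv")
    if len(comparisons_df):
        write_table(comparisons_df, outdir / "scaling_comparisons.csv")
    write_table(growth, outdir / "growth_sgr.csv")
    write_table(growth_summary, outdir / "growth_summary.csv")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    return {
        "fish": fish,
        "morphometry": morph,
        "metabolic": metabolic,
        "analysis": analysis,
        "fits": fits_df,
        "comparisons": comparisons_df,
        "growth": growth,
        "growth_summary": growth_summary,
        "report": report,
    }
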