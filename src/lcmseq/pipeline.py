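"""Stage orchestration: chain simulate -> qc -> quantify -> {bias, model, deg}
-> junctions, writing per-stage TSV tables and one JSON run summary.

Outputs are a pure function of (config, seed): no timestamps, sorted JSON
keys, deterministic float formatting via pandas.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from lcmseq import __version__
from lcmseq.bias import compare_cohorts, stratify_by_rank
from lcmseq.config import STAGE_DEPENDENCIES, PipelineConfig
from lcmseq.deg import two_group_deg
from lcmseq.io import write_count_matrix, write_metadata
from lcmseq.junctions import (
    detectable_mask,
    exon_detection_rates,
    rate_by_exon_count,
    tmm_factors,
    tmm_values,
)
from lcmseq.qc import detect_mixed_profiles, filter_cells, gate_amplification
from lcmseq.quantify import fit_copy_model, to_rpm
from lcmseq.simulate import (
    SimConfig,
    default_ercc_reference,
    gen_ct_plate,
    gen_exon_table,
    gen_fresh_vs_section,
    gen_granulosa_cohort,
    gen_oocyte_cohort,
)
from lcmseq.sizemodel import build_size_model, pc_diameter_association


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages in dependency order; returns the run summary."""
    config.validate_stage_order()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    thr = config.thresholds
    summary: dict[str, Any] = {
        "seed": seed,
        "lcmseq_version": __version__,
        "python_version": sys.version.split()[0],
        "numpy_version": np.__version__,
        "thresholds": dataclasses.asdict(thr),
        "stages_run": [],
    }
    state: dict[str, Any] = {}

    def _require(stage: str) -> None:
        for dep in STAGE_DEPENDENCIES[stage]:
            if dep not in summary["stages_run"]:
                raise RuntimeError(f"stage {stage!r} requires output of {dep!r}")

    if config.stages.get("simulate", False):
        sim_cfg = SimConfig(seed=seed, **config.sim)
        ooc_counts, ooc_meta, ooc_truth = gen_oocyte_cohort(sim_cfg, seed)
        gran_counts, gran_meta, gran_truth = gen_granulosa_cohort(sim_cfg, seed)
        fresh, section, fvs_truth = gen_fresh_vs_section(sim_cfg, seed)
        ct, ct_truth = gen_ct_plate(
            sim_cfg.ct_plate_size, n_failures=sim_cfg.n_retarded, seed=seed
        )
        exon_model, exon_counts, junc_counts, exon_truth = gen_exon_table(seed=seed)
        write_count_matrix(ooc_counts, out / "oocyte_counts.tsv")
        write_count_matrix(gran_counts, out / "granulosa_counts.tsv")
        write_count_matrix(fresh, out / "fresh_counts.tsv")
        write_count_matrix(section, out / "section_counts.tsv")
        write_count_matrix(exon_counts, out / "exon_counts.tsv")
        write_count_matrix(junc_counts, out / "junction_counts.tsv")
        write_metadata(ooc_meta + gran_meta, out / "metadata.tsv")
        exon_model.to_frame().to_csv(out / "exon_model.tsv", sep="\t", index=False)
        pd.DataFrame({"well": range(len(ct)), "ct": ct}).to_csv(
            out / "ct_plate.tsv", sep="\t", index=False
        )
        for name, truth in (
            ("oocyte", ooc_truth),
            ("granulosa", gran_truth),
            ("fresh_vs_section", fvs_truth),
            ("ct_plate", ct_truth),
            ("exon", exon_truth),
        ):
            truth.to_json(out / f"truth_{name}.json")
        state.update(
            ooc_counts=ooc_counts, ooc_meta=ooc_meta, ooc_truth=ooc_truth,
            gran_counts=gran_counts, gran_meta=gran_meta, gran_truth=gran_truth,
            fresh=fresh, section=section, ct=ct,
            exon_model=exon_model, exon_counts=exon_counts, junc_counts=junc_counts,
        )
        summary["stages_run"].append("simulate")
        summary["simulate"] = {
            "n_oocytes": ooc_counts.n_cells,
            "n_granulosa": gran_counts.n_cells,
            "n_genes": len(ooc_counts.gene_ids),
            "n_spikes": len(ooc_counts.spike_ids),
        }

    if config.stages.get("qc", False):
        _require("qc")
        mask, trace = gate_amplification(state["ct"], alpha=thr.grubbs_alpha)
        pd.DataFrame(
            [
                {"iteration": t.iteration, "well": t.well_index,
                 "G": t.statistic, "p": t.p_value}
                for t in trace
            ],
            columns=["iteration", "well", "G", "p"],
        ).to_csv(out / "gate_trace.tsv", sep="\t", index=False)
        ooc_report = filter_cells(state["ooc_meta"], state["ooc_counts"], thr)
        gran_report = filter_cells(state["gran_meta"], state["gran_counts"], thr)
        ooc_log2 = to_rpm(state["ooc_counts"]).log2
        gran_log2 = to_rpm(state["gran_counts"]).log2
        mixed = detect_mixed_profiles(
            gran_log2,
            state["gran_counts"].cell_ids,
            ooc_log2.mean(axis=1),
            thr,
            oocyte_sd_log2=ooc_log2.std(axis=1),
        )
        rows = []
        for rep in (ooc_report, gran_report):
            for c in rep.cell_ids:
                rows.append(
                    {"cell_id": c, "passed": rep.passed[c],
                     "reasons": ";".join(rep.reasons[c])}
                )
        mixed_ids = {m.cell_id for m in mixed if m.mixed}
        for row in rows:
            if row["cell_id"] in mixed_ids:
                row["passed"] = False
                row["reasons"] = ";".join(
                    filter(None, [row["reasons"], "mixed_profile"])
                )
        qc_df = pd.DataFrame(rows).set_index("cell_id")
        qc_df.to_csv(out / "qc_report.tsv", sep="\t")
        state["qc_passed"] = [c for c in qc_df.index if qc_df.loc[c, "passed"]]
        state["mixed_ids"] = mixed_ids
        summary["stages_run"].append("qc")
        summary["qc"] = {
            "n_wells_gated_out": int((~mask).sum()),
            "n_cells_failed": int((~qc_df["passed"]).sum()),
            "n_mixed_profiles": len(mixed_ids),
        }

    if config.stages.get("quantify", False):
        _require("quantify")
        ooc_expr = to_rpm(state["ooc_counts"])
        gran_expr = to_rpm(state["gran_counts"])
        ooc_expr.to_frame().to_csv(out / "oocyte_log2rpm.tsv", sep="\t")
        gran_expr.to_frame().to_csv(out / "granulosa_log2rpm.tsv", sep="\t")
        ref = default_ercc_reference(len(state["ooc_counts"].spike_ids))
        spikes = state["ooc_counts"].spike_counts()
        copy_models = []
        for c in range(spikes.shape[1]):
            copy_models.append(fit_copy_model(spikes[:, c], ref))
        pd.DataFrame(
            {
                "cell_id": state["ooc_counts"].cell_ids,
                "slope": [m.slope for m in copy_models],
                "intercept": [m.intercept for m in copy_models],
                "n_spikes_used": [m.n_spikes_used for m in copy_models],
            }
        ).to_csv(out / "copy_models.tsv", sep="\t", index=False)
        state["ooc_expr"] = ooc_expr
        state["gran_expr"] = gran_expr
        summary["stages_run"].append("quantify")
        summary["quantify"] = {
            "mean_copy_slope": float(np.mean([m.slope for m in copy_models])),
        }

    if config.stages.get("bias", False):
        _require("bias")
        fresh, section = state["fresh"], state["section"]
        fresh_log2 = to_rpm(fresh).log2
        section_log2 = to_rpm(section).log2
        report = compare_cohorts(
            fresh.gene_counts(), section.gene_counts(),
            fresh_log2, section_log2, fresh.gene_ids,
            alpha=thr.bias_alpha, min_log2_diff=thr.bias_min_log2_diff,
        )
        report.table.to_csv(out / "bias_report.tsv", sep="\t")
        stratify_by_rank(report, n_bins=10).to_csv(out / "bias_by_rank.tsv", sep="\t")
        summary["stages_run"].append("bias")
        summary["bias"] = {
            "n_detection_error_flags": int(report.table["detection_error_flag"].sum()),
            "n_bias_flags": int(report.table["bias_flag"].sum()),
        }

    if config.stages.get("model", False):
        _require("model")
        expr = state["ooc_expr"]
        diameters = np.array(
            [r.diameter_um for r in state["ooc_meta"]], dtype=float
        )
        model, matches = build_size_model(
            expr.log2,
            expr.gene_ids,
            expr.cell_ids,
            diameters,
            grid_um=np.array(config.diameter_grid.bins()),
            min_log2=thr.pca_floor_log2,
            deviation_cut_um=thr.deviation_cut_um,
        )
        matches.table.to_csv(out / "size_model_matches.tsv", sep="\t")
        pd.DataFrame(
            model.reconstruction,
            index=model.gene_ids,
            columns=[f"d{int(d)}" for d in model.grid_um],
        ).to_csv(out / "size_model_reconstruction.tsv", sep="\t")
        with open(out / "size_model.json", "w") as fh:
            json.dump(
                {
                    "coef": model.coef.tolist(),
                    "grid_um": model.grid_um.tolist(),
                    "explained_variance_ratio":
                        model.pca.explained_variance_ratio.tolist(),
                    "pc_diameter_rs": pc_diameter_association(
                        model.pca.scores,
                        diameters[
                            [expr.cell_ids.index(c) for c in model.pca.cell_ids]
                        ],
                    ).tolist(),
                },
                fh, indent=1, sort_keys=True,
            )
        summary["stages_run"].append("model")
        summary["model"] = {
            "n_oocytes_analyzed": len(expr.cell_ids),
            "n_model_genes": len(model.gene_ids),
            "n_deviant": int(matches.table["deviant"].sum()),
            "n_retarded": int(matches.table["retarded"].sum()),
        }

    if config.stages.get("deg", False):
        _require("deg")
        gran_expr = state["gran_expr"]
        positions = np.array(
            [r.position for r in state["gran_meta"]], dtype=object
        )
        keep = np.ones(len(positions), dtype=bool)
        if "mixed_ids" in state:
            keep = np.array(
                [c not in state["mixed_ids"] for c in gran_expr.cell_ids]
            )
        result = two_group_deg(
            gran_expr.log2[:, keep],
            gran_expr.gene_ids,
            positions[keep] == "neighboring",
            diff_cut=thr.deg_diff_cut,
            floor_log2=thr.deg_floor_log2,
            alpha=thr.deg_alpha,
            q_cut=thr.deg_q_cut,
        )
        result.table.to_csv(out / "deg_granulosa.tsv", sep="\t")
        summary["stages_run"].append("deg")
        summary["deg"] = {
            "n_tested": result.n_genes_tested,
            "n_up_neighboring": int(
                ((result.table["direction"] == "up")).sum()
            ),
            "n_up_nonneighboring": int(
                ((result.table["direction"] == "down")).sum()
            ),
        }

    if config.stages.get("junctions", False):
        _require("junctions")
        exon_counts = state["exon_counts"]
        tmm = tmm_factors(
            exon_counts.counts,
            logratio_trim=thr.tmm_logratio_trim,
            abs_trim=thr.tmm_abs_trim,
            sample_ids=exon_counts.cell_ids,
        )
        values = tmm_values(exon_counts.counts, tmm)
        mask = detectable_mask(values, cut=thr.tmm_detect_cut)
        rates = exon_detection_rates(mask, exon_counts.feature_ids, state["exon_model"])
        rates.table.to_csv(out / "exon_detection_rates.tsv", sep="\t")
        rate_by_exon_count(rates, [1, 5, 10, 20, 50]).to_csv(
            out / "rate_by_exon_count.tsv", sep="\t"
        )
        summary["stages_run"].append("junctions")
        summary["junctions"] = {
            "mean_exon_detection_rate": float(rates.table["detection_rate"].mean()),
            "tmm_reference": int(tmm.reference_index),
        }

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
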