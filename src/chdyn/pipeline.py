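"""End-to-end pipeline: simulate -> classify -> attribute -> germline HRD ->
fitness -> single cell -> cohort statistics.

A single :class:`PipelineConfig` (loadable from YAML) carries the input
paths, every analysis threshold with its published default, gene-list
overrides and the seed.  ``run_pipeline`` writes TSV outputs per stage plus a
JSON manifest recording the package version, seed, thresholds (with any
overrides highlighted) and per-stage record counts, so reruns are auditable
and seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import chdyn
from chdyn.attribution import VARIANT_KEY, build_trajectories, merge_paired_tables
from chdyn.config import Thresholds
from chdyn.filtering import call_ch_status, classify_calls
from chdyn.fitness import (
    count_threshold_crossings,
    fit_fitness_table,
    gene_fitness_summary,
)
from chdyn.germline import classify_germline_table, patient_hrd_status
from chdyn.genes import default_ch_genes, default_hr_genes, read_gene_list
from chdyn.singlecell import call_clones, clone_table, qc_sample
from chdyn.stats import baseline_table, cooccurrence_matrix, vaf_concordance
from chdyn.synthetic import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "chdyn_out"
    seed: int = 0
    simulate: bool = True
    n_patients: int = 40
    variants_path: str | None = None     # used when simulate=False
    patients_path: str | None = None
    ch_gene_list: str | None = None      # path; None = packaged default
    hr_gene_list: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    run_single_cell: bool = True
    sc_n_cells: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


def _write(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    ch_genes = (
        read_gene_list(config.ch_gene_list) if config.ch_gene_list else default_ch_genes()
    )
    hr_genes = (
        read_gene_list(config.hr_gene_list) if config.hr_gene_list else default_hr_genes()
    )
    manifest: dict = {
        "package": "chdyn",
        "version": chdyn.__version__,
        "seed": config.seed,
        "thresholds": thr.as_dict(),
        "threshold_overrides": thr.overrides(),
        "stages": {},
    }

    # 1. input: simulate or load
    if config.simulate:
        sim_cfg = SimulationConfig(n_patients=config.n_patients, seed=config.seed)
        cohort = simulate_cohort(sim_cfg)
        variants, patients, pileup = cohort.variants, cohort.patients, cohort.pileup
        _write(cohort.truth, out / "truth.tsv")
        _write(pileup, out / "pileup.tsv")
        timepoints = sim_cfg.timepoints_years
    else:
        if not config.variants_path or not config.patients_path:
            raise FileNotFoundError(
                "stage 'input': variants_path and patients_path are required "
                "when simulate is false"
            )
        from chdyn.io import read_variant_table

        variants = read_variant_table(config.variants_path)
        patients = pd.read_csv(config.patients_path, sep="\t")
        pileup = variants
        timepoints = tuple(sorted(variants["timepoint_years"].unique()))
    manifest["stages"]["simulate" if config.simulate else "load"] = {
        "variants": len(variants), "patients": len(patients),
    }

    # 2. classification cascade
    classified = classify_calls(
        variants, hr_genes=hr_genes, ch_genes=ch_genes, thresholds=thr
    )
    _write(classified, out / "classified.tsv")
    audit = classified[classified["category"] != "somatic"][
        VARIANT_KEY + ["source", "timepoint_years", "category", "filter_reason"]
    ]
    _write(audit, out / "exclusion_audit.tsv")
    ch_rows = []
    baseline_wb = classified[
        (classified["source"] == "WB")
        & (classified["timepoint_years"] == timepoints[0])
    ]
    for pid, grp in baseline_wb.groupby("patient_id"):
        st = call_ch_status(grp, ch_genes, thresholds=thr)
        ch_rows.append(dict(patient_id=pid, ch_positive=st.positive,
                            max_vaf=st.max_vaf, n_mutations=st.n_mutations))
    ch_status = pd.DataFrame(
        ch_rows, columns=["patient_id", "ch_positive", "max_vaf", "n_mutations"]
    )
    patients = patients.merge(ch_status, on="patient_id", how="left")
    patients["ch_positive"] = (
        patients["ch_positive"].astype("boolean").fillna(False).astype(bool)
    )
    patients[["max_vaf", "n_mutations"]] = (
        patients[["max_vaf", "n_mutations"]].fillna(0)
    )
    _write(patients, out / "patients.tsv")
    manifest["stages"]["classify"] = {
        "calls": len(classified),
        "somatic": int((classified["category"] == "somatic").sum()),
        "ch_positive_patients": int(patients["ch_positive"].sum()),
    }

    # 3. paired WB/cfDNA attribution at baseline + serial trajectories
    somatic = classified[classified["category"] == "somatic"]
    wb0 = somatic[(somatic["source"] == "WB") & (somatic["timepoint_years"] == timepoints[0])]
    cf0 = somatic[(somatic["source"] == "cfDNA") & (somatic["timepoint_years"] == timepoints[0])]
    paired = merge_paired_tables(wb0, cf0, thresholds=thr)
    paired = paired[paired["included"]]
    _write(paired, out / "origin_attribution.tsv")
    trajectories = build_trajectories(
        somatic, timepoints=timepoints, pileup=pileup, thresholds=thr
    )
    origin_map = paired.set_index(
        [c for c in VARIANT_KEY]
    )["origin"]
    traj_keys = pd.MultiIndex.from_frame(trajectories[VARIANT_KEY])
    trajectories["origin"] = [
        origin_map.get(k, "") for k in traj_keys
    ]
    _write(trajectories, out / "trajectories.tsv")
    manifest["stages"]["attribute"] = {
        "paired_included": len(paired),
        "non_hematopoietic": int((paired["origin"] == "non_hematopoietic").sum()),
        "trajectory_rows": len(trajectories),
    }

    # 4. germline HRD
    germline_rows = classified[classified["category"] == "germline"].drop_duplicates(
        subset=VARIANT_KEY
    )
    germline_classified = classify_germline_table(
        germline_rows, hr_gene_list=hr_genes, thresholds=thr
    )
    hrd = patient_hrd_status(germline_classified)
    _write(germline_classified, out / "germline_report.tsv")
    _write(hrd, out / "hrd_status.tsv")
    manifest["stages"]["germline_hrd"] = {
        "germline_variants": len(germline_classified),
        "hrd_positive_patients": int(hrd["hrd_status"].sum()) if len(hrd) else 0,
    }

    # 5. clonal fitness: overall from WB pairs; per-phase from cfDNA 3-point
    hema = trajectories[trajectories["origin"] != "non_hematopoietic"]
    wb_traj = hema[hema["source"] == "WB"]
    overall = fit_fitness_table(wb_traj, thresholds=thr)
    cf_traj = hema[hema["source"] == "cfDNA"]
    per_phase = fit_fitness_table(cf_traj, per_phase=True, thresholds=thr)
    fitness = pd.concat([overall, per_phase], ignore_index=True)
    _write(fitness, out / "fitness.tsv")
    _write(gene_fitness_summary(fitness), out / "fitness_by_gene.tsv")
    crossings = count_threshold_crossings(overall, thresholds=thr)
    _write(crossings, out / "threshold_crossings.tsv")
    manifest["stages"]["fitness"] = {
        "overall_estimates": len(overall),
        "per_phase_estimates": len(per_phase),
    }

    # 6. single cell (optional, simulated input)
    if config.run_single_cell:
        from chdyn.synthetic import simulate_genotype_matrix

        rng = np.random.default_rng(config.seed + 1)
        clones_spec = [((1, 0), 0.3), ((0, 1), 0.2)]
        matrix, _ = simulate_genotype_matrix(
            clones_spec, config.sc_n_cells, 0.05, 0.05, rng,
            variant_ids=["PPM1D_mut", "TP53_mut"],
        )
        qc = qc_sample(matrix, thresholds=thr)
        clones = call_clones(matrix, thresholds=thr) if qc.passed else []
        _write(clone_table(clones, list(matrix.columns)), out / "sc_clones.tsv")
        manifest["stages"]["single_cell"] = {
            "qc_passed": qc.passed,
            "genotyped_cells": qc.genotyped_cells,
            "clones": max(0, len(clones) - 1),
        }
    else:
        manifest["stages"]["single_cell"] = {"skipped": True}

    # 7. cohort statistics
    stats_summary: dict = {}
    base = baseline_table(
        patients, "ch_positive",
        {"age": "numeric", "arm": "categorical", "prior_lines": "categorical",
         "prior_parpi": "categorical"},
    )
    _write(base, out / "baseline_table.tsv")
    stats_summary["baseline_p_values"] = dict(zip(base["variable"], base["p_value"]))
    somatic_wb0 = baseline_wb[baseline_wb["category"] == "somatic"]
    multi = somatic_wb0.groupby("patient_id").size()
    if (multi >= 2).sum() >= 5 and somatic_wb0["gene"].nunique() >= 2:
        cooc = cooccurrence_matrix(somatic_wb0)
        _write(cooc, out / "cooccurrence.tsv")
        stats_summary["cooccurrence_pairs"] = int(len(cooc) // 2)
    both = paired[(paired["wb_vaf"] > 0) & (paired["cf_vaf"] > 0)]
    hema_pairs = both[both["origin"] == "hematopoietic"]
    if len(hema_pairs) >= 3:
        r, n = vaf_concordance(hema_pairs["wb_vaf"], hema_pairs["cf_vaf"])
        stats_summary["wb_cf_pearson_r"] = r
        stats_summary["wb_cf_pairs"] = n
    manifest["stages"]["cohort_stats"] = stats_summary

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
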