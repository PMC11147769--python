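"""Synthetic cohort generator.

No patient-level data from the motivating study is publicly deposited, so the
package ships a generator that emulates the statistical structure the
analysis assumes: CH clones with gene-class-specific fitness growing as
sigmoids through a chemotherapy phase and a PARP-inhibitor maintenance phase,
three serial sampling timepoints, binomial sequencing noise on error-corrected
consensus reads, germline variants near 50% VAF, tumor-shed cfDNA-only
variants, and single-cell genotype matrices with allele dropout and doublets.
Every emitted observation carries a ground-truth label, so recovery of
classification, origin, and fitness can be measured exactly.

Units: VAFs are fractions, times are years, fitness is per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from chdyn.fitness import sigmoid_vaf, solve_A

__all__ = [
    "SimulationConfig",
    "TrueClone",
    "SyntheticCohort",
    "simulate_trajectory",
    "sample_read_counts",
    "simulate_cohort",
    "simulate_genotype_matrix",
    "simulate_pooled_snp_matrix",
]

# Per-gene fitness priors: gene -> ((mean, sd) chemotherapy phase,
#                                   (mean, sd) maintenance phase), in /year.
# DDR genes get high fitness under carboplatin; PPM1D fitness drops under
# PARPi maintenance while TP53 stays high; DTA genes drift slowly throughout.
DEFAULT_GENE_FITNESS_PRIORS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "PPM1D": ((1.93, 0.6), (0.36, 0.6)),
    "TP53": ((1.5, 0.6), (1.5, 0.6)),
    "CHEK2": ((0.8, 0.5), (0.4, 0.5)),
    "ATM": ((0.7, 0.5), (0.4, 0.5)),
    "DNMT3A": ((0.1, 0.3), (0.1, 0.3)),
    "TET2": ((0.1, 0.3), (0.1, 0.3)),
    "ASXL1": ((0.1, 0.3), (0.1, 0.3)),
}

# Relative frequency with which CH clones hit each gene (DDR-heavy cohort of
# heavily pre-treated patients rather than ageing-related DTA dominance).
_CH_GENE_WEIGHTS = {
    "PPM1D": 0.34,
    "DNMT3A": 0.24,
    "TET2": 0.11,
    "CHEK2": 0.09,
    "TP53": 0.07,
    "ATM": 0.05,
    "ASXL1": 0.10,
}

_TUMOR_GENES = ("TP53", "BRCA1", "BRCA2", "RAD51C", "PALB2", "BRIP1")
_TUMOR_GENE_WEIGHTS = (0.5, 0.15, 0.15, 0.07, 0.07, 0.06)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"

VARIANT_TABLE_COLUMNS = [
    "patient_id", "sample_id", "source", "timepoint_years", "chrom", "pos",
    "ref", "alt", "gene", "protein_change", "effect", "vaf", "alt_reads",
    "depth", "dbsnp", "gnomad_af", "clinvar", "enigma",
]

TRUTH_TABLE_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "protein_change",
    "true_category", "true_origin", "v0", "s_phase1", "s_phase2",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for cohort simulation.

    Defaults mirror the assumed study design: three samples per patient at
    treatment start, maintenance start and end of treatment (0 / 0.5 / 1.0
    years, matching median phase durations just under six months each);
    consensus-read depths of ~2000x (WB) and ~1500x (cfDNA); roughly half the
    patients with detectable tumor-derived cfDNA variants.
    """

    n_patients: int = 40
    timepoints_years: tuple[float, ...] = (0.0, 0.5, 1.0)
    wb_depth: float = 2000.0
    cf_depth: float = 1500.0
    gene_fitness_priors: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FITNESS_PRIORS)
    )
    tumor_shed_fraction: float = 0.5
    ado_rate: float = 0.1
    doublet_rate: float = 0.08
    ch_prevalence: float = 0.57
    germline_fraction: float = 0.35
    mean_clones_per_ch_patient: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumor_shed_fraction", "ado_rate", "doublet_rate",
                     "ch_prevalence", "germline_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.wb_depth <= 0 or self.cf_depth <= 0:
            raise ValueError("depths must be positive")
        tps = tuple(self.timepoints_years)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError(f"timepoints must be strictly increasing: {tps}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


@dataclass(frozen=True)
class TrueClone:
    """Ground truth for one somatic CH clone."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    protein_change: str
    v0: float
    s_by_phase: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.v0 < 0.5:
            raise ValueError(f"v0 must lie in (0, 0.5), got {self.v0}")


@dataclass
class SyntheticCohort:
    """Simulated cohort: truth plus the noisy observations the pipeline sees.

    Attributes
    ----------
    patients : clinical covariates, one row per patient.
    variants : called variant observations (long format, WB and cfDNA rows per
        timepoint), schema ``VARIANT_TABLE_COLUMNS``.  A variant appears only
        where its observed VAF reached the 0.1% calling floor.
    pileup : every simulated observation including sub-threshold ones (same
        schema); stands in for manual review of raw pileups.
    truth : per-variant ground truth (category, origin, v0, per-phase s).
    clones : the somatic TrueClone records.
    """

    config: SimulationConfig
    patients: pd.DataFrame
    variants: pd.DataFrame
    pileup: pd.DataFrame
    truth: pd.DataFrame
    clones: list[TrueClone]


def simulate_trajectory(
    v0: float,
    s_by_phase: float | Sequence[tuple[float, float]],
    eval_times: Sequence[float],
) -> np.ndarray:
    """True VAFs of a clone along a piecewise-sigmoid trajectory.

    ``s_by_phase`` is either a single fitness (one unbounded phase) or a list
    of (duration_years, s) segments; within each segment the clone follows
    v(t) = (1/2)/(1 + A e^{-s t}) with A re-anchored so the segment starts at
    the previous segment's end VAF, making the trajectory continuous.
    """
    if not 0.0 < v0 < 0.5:
        raise ValueError(f"v0 must lie in (0, 0.5), got {v0}")
    if np.isscalar(s_by_phase):
        phases = [(float("inf"), float(s_by_phase))]
    else:
        phases = [(float(d), float(s)) for d, s in s_by_phase]
        if any(d < 0 for d, _ in phases):
            raise ValueError("phase durations must be non-negative")

    eval_times = np.asarray(eval_times, dtype=float)
    out = np.empty_like(eval_times)
    for i, t in enumerate(eval_times):
        v = v0
        remaining = float(t)
        for duration, s in phases:
            step = min(remaining, duration)
            v = sigmoid_vaf(step, v, s)
            remaining -= step
            if remaining <= 0:
                break
        else:
            if remaining > 0:  # beyond the last phase: hold the final rate
                v = sigmoid_vaf(remaining, v, phases[-1][1])
        out[i] = v
    return out


def sample_read_counts(
    true_vaf: float, depth: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomial consensus-read sampling: alt ~ Binomial(depth, true_vaf)."""
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError(f"true_vaf must lie in [0, 1], got {true_vaf}")
    depth = int(depth)
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    return int(rng.binomial(depth, true_vaf)), depth


def _random_variant_site(rng: np.random.Generator) -> tuple[str, int, str, str]:
    chrom = f"chr{rng.integers(1, 23)}"
    pos = int(rng.integers(10_000, 50_000_000))
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    return chrom, pos, ref, alt


def _random_protein_change(rng: np.random.Generator) -> str:
    ref = _AA[rng.integers(len(_AA))]
    alt = _AA[rng.integers(len(_AA))]
    return f"{ref}{int(rng.integers(20, 900))}{alt}"


def _phase_durations(timepoints: tuple[float, ...]) -> list[float]:
    return [b - a for a, b in zip(timepoints, timepoints[1:])]


class _CohortBuilder:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.rows: list[dict] = []
        self.truth: list[dict] = []
        self.clones: list[TrueClone] = []
        self.used_sites: set[tuple[str, int]] = set()

    def site(self) -> tuple[str, int, str, str]:
        while True:
            chrom, pos, ref, alt = _random_variant_site(self.rng)
            if (chrom, pos) not in self.used_sites:
                self.used_sites.add((chrom, pos))
                return chrom, pos, ref, alt

    def emit(self, patient_id, source, timepoint, variant, true_vaf, depth_mean):
        """One sequenced observation: Poisson depth, binomial alt reads."""
        depth = max(1, int(self.rng.poisson(depth_mean)))
        alt_reads, depth = sample_read_counts(true_vaf, depth, self.rng)
        vaf = alt_reads / depth
        self.rows.append(
            dict(
                patient_id=patient_id,
                sample_id=f"{patient_id}_{source}_t{timepoint:g}",
                source=source,
                timepoint_years=timepoint,
                vaf=vaf,
                alt_reads=alt_reads,
                depth=depth,
                **variant,
            )
        )

    def record_truth(self, patient_id, variant, category, origin, v0, s_phases):
        self.truth.append(
            dict(
                patient_id=patient_id,
                chrom=variant["chrom"],
                pos=variant["pos"],
                ref=variant["ref"],
                alt=variant["alt"],
                gene=variant["gene"],
                protein_change=variant["protein_change"],
                true_category=category,
                true_origin=origin,
                v0=v0,
                s_phase1=s_phases[0] if s_phases else np.nan,
                s_phase2=s_phases[1] if len(s_phases) > 1 else np.nan,
            )
        )

    # --- per-patient simulation ------------------------------------------

    def add_ch_clones(self, pid: str) -> bool:
        cfg, rng = self.cfg, self.rng
        has_ch = rng.random() < cfg.ch_prevalence
        if not has_ch:
            return False
        n_clones = 1 + rng.poisson(cfg.mean_clones_per_ch_patient - 1.0)
        genes = list(_CH_GENE_WEIGHTS)
        weights = np.array([_CH_GENE_WEIGHTS[g] for g in genes])
        weights = weights / weights.sum()
        durations = _phase_durations(cfg.timepoints_years)
        for _ in range(n_clones):
            gene = genes[rng.choice(len(genes), p=weights)]
            priors = cfg.gene_fitness_priors.get(gene, ((0.0, 0.3), (0.0, 0.3)))
            s_phases = tuple(
                float(rng.normal(mean, sd)) for (mean, sd) in priors
            )
            v0 = float(np.exp(rng.uniform(np.log(0.005), np.log(0.12))))
            chrom, pos, ref, alt = self.site()
            clone = TrueClone(
                patient_id=pid, gene=gene, chrom=chrom, pos=pos, ref=ref,
                alt=alt, protein_change=_random_protein_change(rng),
                v0=v0, s_by_phase=s_phases,
            )
            self.clones.append(clone)
            variant = dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                protein_change=clone.protein_change, effect="nonsynonymous",
                dbsnp=False, gnomad_af=np.nan, clinvar="", enigma="",
            )
            traj = simulate_trajectory(
                v0, list(zip(durations, s_phases)), cfg.timepoints_years
            )
            for tp, v in zip(cfg.timepoints_years, traj):
                self.emit(pid, "WB", tp, variant, v, cfg.wb_depth)
                self.emit(pid, "cfDNA", tp, variant, v, cfg.cf_depth)
            self.record_truth(pid, variant, "somatic", "hematopoietic", v0, s_phases)
        return True

    def add_tumor_variants(self, pid: str) -> None:
        """Tumor-shed cfDNA-only variants: true WB VAF is exactly 0."""
        cfg, rng = self.cfg, self.rng
        n_vars = 1 + rng.poisson(0.7)
        durations = _phase_durations(cfg.timepoints_years)
        for _ in range(n_vars):
            gene = rng.choice(_TUMOR_GENES, p=_TUMOR_GENE_WEIGHTS)
            # responding tumors shrink under carboplatin; mixed maintenance
            s_phases = (float(rng.normal(-3.0, 2.0)), float(rng.normal(0.0, 1.5)))
            v0 = float(np.exp(rng.uniform(np.log(0.01), np.log(0.2))))
            chrom, pos, ref, alt = self.site()
            variant = dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=str(gene),
                protein_change=_random_protein_change(rng),
                effect="nonsynonymous", dbsnp=False, gnomad_af=np.nan,
                clinvar="", enigma="",
            )
            traj = simulate_trajectory(
                v0, list(zip(durations, s_phases)), cfg.timepoints_years
            )
            for tp, v in zip(cfg.timepoints_years, traj):
                self.emit(pid, "WB", tp, variant, 0.0, cfg.wb_depth)
                self.emit(pid, "cfDNA", tp, variant, v, cfg.cf_depth)
            self.record_truth(
                pid, variant, "somatic", "non_hematopoietic", v0, s_phases
            )

    def add_germline(self, pid: str) -> None:
        """Heterozygous germline variant at true VAF 0.5 in both sources."""
        cfg, rng = self.cfg, self.rng
        gene = rng.choice(["BRCA1", "BRCA2", "RAD51C", "PALB2"], p=[0.4, 0.4, 0.1, 0.1])
        pathogenic = rng.random() < 0.6
        if pathogenic:
            effect = str(rng.choice(["stopgain", "splice", "truncating_indel"]))
            clinvar = str(rng.choice(["pathogenic", "likely_pathogenic", ""]))
            gnomad = float(10 ** rng.uniform(-6, -3))
        else:
            effect = "nonsynonymous"
            clinvar = ""
            gnomad = float(10 ** rng.uniform(-4, -2))
        chrom, pos, ref, alt = self.site()
        variant = dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=str(gene),
            protein_change=_random_protein_change(rng), effect=effect,
            dbsnp=False, gnomad_af=gnomad, clinvar=clinvar, enigma="",
        )
        for tp in cfg.timepoints_years:
            self.emit(pid, "WB", tp, variant, 0.5, cfg.wb_depth)
            self.emit(pid, "cfDNA", tp, variant, 0.5, cfg.cf_depth)
        label = "germline_pathogenic" if pathogenic else "germline_benign"
        self.record_truth(pid, variant, label, "germline", 0.5, ())

    def add_snp_decoy(self, pid: str) -> None:
        """Common SNP at a mapping-biased ~43% observed VAF, dbSNP-flagged."""
        cfg, rng = self.cfg, self.rng
        chrom, pos, ref, alt = self.site()
        variant = dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene="OTHERGENE",
            protein_change=_random_protein_change(rng), effect="nonsynonymous",
            dbsnp=True, gnomad_af=float(rng.uniform(0.05, 0.5)),
            clinvar="", enigma="",
        )
        true_vaf = float(rng.uniform(0.41, 0.445))
        for tp in cfg.timepoints_years:
            self.emit(pid, "WB", tp, variant, true_vaf, cfg.wb_depth)
            self.emit(pid, "cfDNA", tp, variant, true_vaf, cfg.cf_depth)
        self.record_truth(pid, variant, "snp", "germline", true_vaf, ())

    def add_filtered_decoy(self, pid: str) -> None:
        """Synonymous call that the retention filter must drop."""
        cfg, rng = self.cfg, self.rng
        chrom, pos, ref, alt = self.site()
        variant = dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=str(rng.choice(["DNMT3A", "TET2", "OTHERGENE"])),
            protein_change=f"{_AA[rng.integers(20)]}{int(rng.integers(20, 900))}=",
            effect="synonymous", dbsnp=False, gnomad_af=np.nan,
            clinvar="", enigma="",
        )
        true_vaf = float(rng.uniform(0.01, 0.2))
        for tp in cfg.timepoints_years:
            self.emit(pid, "WB", tp, variant, true_vaf, cfg.wb_depth)
        self.record_truth(pid, variant, "filtered", "hematopoietic", true_vaf, ())

    def add_patient(self, pid: str) -> dict:
        cfg, rng = self.cfg, self.rng
        has_ch = self.add_ch_clones(pid)
        if rng.random() < cfg.tumor_shed_fraction:
            self.add_tumor_variants(pid)
        if rng.random() < cfg.germline_fraction:
            self.add_germline(pid)
        if rng.random() < 0.5:
            self.add_snp_decoy(pid)
        if rng.random() < 0.5:
            self.add_filtered_decoy(pid)
        age = float(np.round(rng.normal(68 if has_ch else 56, 7), 1))
        prior_lines = ">1" if rng.random() < (0.55 if has_ch else 0.24) else "1"
        prior_parpi = bool(rng.random() < (0.45 if has_ch else 0.08))
        return dict(
            patient_id=pid,
            age=age,
            arm=str(rng.choice(["A", "B", "C"])),
            prior_lines=prior_lines,
            prior_parpi=prior_parpi,
            prior_parpi_months=float(np.round(rng.uniform(6, 36), 1)) if prior_parpi else 0.0,
            ch_truth=has_ch,
        )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a full cohort with ground truth; deterministic in config.seed."""
    builder = _CohortBuilder(config)
    patients = [
        builder.add_patient(f"P{i:03d}") for i in range(config.n_patients)
    ]
    patient_df = pd.DataFrame(patients, columns=[
        "patient_id", "age", "arm", "prior_lines", "prior_parpi",
        "prior_parpi_months", "ch_truth",
    ])
    pileup = pd.DataFrame(builder.rows, columns=VARIANT_TABLE_COLUMNS)
    # variant calling floor: a variant is called where observed VAF >= 0.1%
    called = pileup[(pileup["alt_reads"] >= 1) & (pileup["vaf"] >= 0.001)]
    truth = pd.DataFrame(builder.truth, columns=TRUTH_TABLE_COLUMNS)
    return SyntheticCohort(
        config=config,
        patients=patient_df,
        variants=called.reset_index(drop=True),
        pileup=pileup,
        truth=truth,
        clones=builder.clones,
    )


# --- single-cell simulation ----------------------------------------------


def _apply_ado(genotypes: np.ndarray, ado_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Allele dropout: each of the two alleles drops independently.

    het with one allele dropped is miscalled hom (0 or 2); both dropped is
    missing (NaN); hom/wt with one allele dropped keeps its call.
    """
    g = genotypes.astype(float)
    allele1 = (g >= 1).astype(float)   # first allele carries alt iff g >= 1
    allele2 = (g == 2).astype(float)
    drop1 = rng.random(g.shape) < ado_rate
    drop2 = rng.random(g.shape) < ado_rate
    both = drop1 & drop2
    out = np.where(drop1, 2 * allele2, np.where(drop2, 2 * allele1, g))
    out = out.astype(float)
    out[both] = np.nan
    return out


def simulate_genotype_matrix(
    clones: Sequence[tuple[Sequence[int], float]],
    n_cells: int,
    ado_rate: float,
    doublet_rate: float,
    rng: np.random.Generator,
    *,
    variant_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cells x variants genotype matrix.

    ``clones`` is a list of (genotype vector over variants with values
    0/1/2, cell fraction); the remaining fraction is wild-type (C0).  Each
    barcode is a doublet with probability ``doublet_rate``, merging two
    independently drawn cells by the per-locus maximum.  Allele dropout then
    corrupts each allele independently with probability ``ado_rate``.

    Returns (matrix, truth): the matrix has NaN for missing genotypes; truth
    records each barcode's drawn clone indices (-1 = wild type) and doublet
    flag.
    """
    fracs = np.array([f for _, f in clones], dtype=float)
    if fracs.size and (fracs < 0).any():
        raise ValueError("clone fractions must be non-negative")
    total = fracs.sum()
    if total > 1.0 + 1e-12:
        raise ValueError(f"clone fractions sum to {total} > 1")
    geno = np.array([list(g) for g, _ in clones], dtype=float)
    n_var = geno.shape[1] if geno.size else (len(variant_ids) if variant_ids else 0)
    if not set(np.unique(geno)).issubset({0.0, 1.0, 2.0}) and geno.size:
        raise ValueError("clone genotypes must be 0 (wt), 1 (het) or 2 (hom)")
    # index len(clones) = wild type
    probs = np.append(fracs, 1.0 - total)
    bank = np.vstack([geno, np.zeros((1, n_var))]) if n_var else np.zeros((1, 0))

    first = rng.choice(len(probs), size=n_cells, p=probs)
    is_doublet = rng.random(n_cells) < doublet_rate
    second = rng.choice(len(probs), size=n_cells, p=probs)
    second = np.where(is_doublet, second, first)

    merged = np.maximum(bank[first], bank[second])
    observed = _apply_ado(merged, ado_rate, rng)

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    if variant_ids is None:
        variant_ids = [f"var{j}" for j in range(n_var)]
    matrix = pd.DataFrame(observed, index=cell_ids, columns=list(variant_ids))
    wt_idx = len(clones)
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "clone_1": np.where(first == wt_idx, -1, first),
            "clone_2": np.where(second == wt_idx, -1, second),
            "is_doublet": is_doublet,
        }
    )
    return matrix, truth


def simulate_pooled_snp_matrix(
    profiles: np.ndarray,
    n_cells: int,
    ado_rate: float,
    doublet_rate: float,
    rng: np.random.Generator,
    *,
    snp_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled-sample SNP genotypes for demultiplexing tests.

    ``profiles`` is (n_samples x n_snps) with values 0/1/2; cells are drawn
    uniformly from the samples, doublets merge two samples' profiles by the
    per-locus maximum, and ADO applies as in ``simulate_genotype_matrix``.
    Truth labels carry each barcode's source sample(s).
    """
    profiles = np.asarray(profiles, dtype=float)
    n_samples = profiles.shape[0]
    first = rng.integers(n_samples, size=n_cells)
    is_doublet = rng.random(n_cells) < doublet_rate
    second = rng.integers(n_samples, size=n_cells)
    second = np.where(is_doublet, second, first)
    merged = np.maximum(profiles[first], profiles[second])
    observed = _apply_ado(merged, ado_rate, rng)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(profiles.shape[1])]
    matrix = pd.DataFrame(observed, index=cell_ids, columns=list(snp_ids))
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_1": first,
            "sample_2": second,
            "is_doublet": is_doublet,
        }
    )
    return matrix, truth
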