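"""Analysis thresholds.

Every numeric constant of the analysis lives here with its published default,
so stage logic never hard-codes a cutoff and a pipeline run can log overrides.
VAFs are fractions in [0, 1] throughout the package; percent thresholds are
converted exactly once, here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs of the variant-classification and dynamics analysis.

    Attributes
    ----------
    germline_vaf
        Variants with VAF strictly above this are classified germline (0.45).
    snp_vaf
        VAF floor (strict) for the dbSNP/gnomAD SNP-exclusion rule (0.40).
    snp_pop_af
        Population allele-frequency cutoff (strict >) marking a common SNP (0.01).
    ch_vaf
        Minimum VAF (inclusive) for a somatic CH-gene mutation to count toward
        patient CH status (0.01).
    paired_inclusion_vaf
        Paired WB/cfDNA inclusion: single-source VAF, or the sum of both
        sources' VAFs, must reach this value (0.008).
    detection_floor
        Variant-calling detection limit; also the VAF imputed to manually
        rescued sub-threshold timepoints (0.001).
    cf_origin_fold
        cfDNA/WB VAF ratio (inclusive) above which a cfDNA variant is called
        non-hematopoietic (5).
    tumor_dynamics_fold
        Fold change (inclusive) defining increasing/decreasing tumor-variant
        dynamics in cfDNA (10).
    fitness_category
        |s| beyond which (strict) a clone is categorized increasing or
        decreasing, in /year (0.25).
    min_alt_reads
        Minimum alternate consensus-read count (inclusive) for retention (10).
    min_genotyped_cells
        Minimum genotyped cells (inclusive) for a single-cell sample to pass QC
        (400).
    min_clone_cells
        Minimum cells carrying the mutated allele (inclusive) for a clone to be
        reported (5).
    vaf_clamp_high
        Upper clamp applied before fitness estimation; keeps the sigmoid away
        from its singularity at VAF 0.5 (e.g. under loss of heterozygosity).
    pathogenic_pop_af
        Population AF cutoff (strict <) for the deleterious-and-rare germline
        pathogenicity arm (0.01).
    demux_min_concordance
        Minimum SNP-profile concordance for a demultiplexed cell assignment.
    demux_min_margin
        Minimum gap between best and second-best profile concordance.
    """

    germline_vaf: float = 0.45
    snp_vaf: float = 0.40
    snp_pop_af: float = 0.01
    ch_vaf: float = 0.01
    paired_inclusion_vaf: float = 0.008
    detection_floor: float = 0.001
    cf_origin_fold: float = 5.0
    tumor_dynamics_fold: float = 10.0
    fitness_category: float = 0.25
    min_alt_reads: int = 10
    min_genotyped_cells: int = 400
    min_clone_cells: int = 5
    vaf_clamp_high: float = 0.499
    pathogenic_pop_af: float = 0.01
    demux_min_concordance: float = 0.9
    demux_min_margin: float = 0.1

    def replace(self, **overrides: Any) -> "Thresholds":
        return dataclasses.replace(self, **overrides)

    def overrides(self) -> dict[str, Any]:
        """Fields differing from the published defaults (for run manifests)."""
        default = Thresholds()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(default, f.name)
        }

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


DEFAULT_THRESHOLDS = Thresholds()
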