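"""Variant retention and classification cascade.

From annotated variant calls to categories:

* retention — only nonsynonymous coding and splice-site calls with at least
  10 alternate consensus reads survive;
* germline — VAF strictly above 45%;
* SNP exclusion — VAF strictly above 40% and flagged in dbSNP or with gnomAD
  population AF above 1%, unless the site is a recurrent CH driver hotspot;
* everything else retained as somatic.

The cascade is per-call (order-independent) and every exclusion is recorded
with the rule that fired.  Patient-level CH status is positive when at least
one somatic variant in a CH-panel gene reaches 1% VAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chdyn.config import DEFAULT_THRESHOLDS, Thresholds
from chdyn.genes import assign_gene_class, canonical_gene, is_hotspot

__all__ = [
    "apply_retention_filters",
    "classify_call",
    "classify_calls",
    "call_ch_status",
    "CHStatus",
]

RETAINED_EFFECTS = frozenset(
    {"nonsynonymous", "splice", "stopgain", "startloss", "truncating_indel",
     "frameshift"}
)


def _effect_retained(effect: str) -> bool:
    return str(effect).strip().lower() in RETAINED_EFFECTS


def apply_retention_filters(
    calls: pd.DataFrame, *, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Annotate each call with retained (bool) and the filter rule that fired.

    Adds columns ``retained`` and ``filter_reason`` ('' when retained).
    Protein-altering effects (nonsynonymous, splice and other truncating
    classes) with alt_reads >= 10 pass; the hotspot exemption never rescues a
    call failing the read-count floor.
    """
    calls = calls.copy()
    effect_ok = calls["effect"].map(_effect_retained)
    reads_ok = calls["alt_reads"] >= thresholds.min_alt_reads
    reason = np.where(
        ~effect_ok,
        "effect_not_protein_altering",
        np.where(~reads_ok, "alt_reads_below_minimum", ""),
    )
    calls["retained"] = effect_ok & reads_ok
    calls["filter_reason"] = reason
    return calls


def classify_call(
    vaf: float,
    *,
    gene: str,
    protein_change: str,
    dbsnp_snp: bool = False,
    gnomad_af: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Category of a single retained call: germline / snp_excluded / somatic.

    Order matters: the germline rule (VAF > 45%) precedes SNP exclusion
    (VAF > 40% with dbSNP flag or gnomAD AF > 1%), and hotspot sites are
    exempt from SNP exclusion but not from the germline rule.
    """
    if vaf > thresholds.germline_vaf:
        return "germline"
    common = bool(dbsnp_snp) or (
        gnomad_af is not None
        and not (isinstance(gnomad_af, float) and np.isnan(gnomad_af))
        and gnomad_af > thresholds.snp_pop_af
    )
    if vaf > thresholds.snp_vaf and common and not is_hotspot(gene, protein_change):
        return "snp_excluded"
    return "somatic"


def classify_calls(
    calls: pd.DataFrame,
    *,
    hr_genes=None,
    ch_genes=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Run the full cascade on a variant table.

    Returns the table with added columns: category ('filtered', 'germline',
    'snp_excluded', 'somatic'), hotspot, gene_class and filter_reason.  Every
    input row appears exactly once in the output.
    """
    out = apply_retention_filters(calls, thresholds=thresholds)
    out["gene"] = out["gene"].map(canonical_gene)
    out["hotspot"] = [
        is_hotspot(g, p) for g, p in zip(out["gene"], out["protein_change"])
    ]
    gnomad = out["gnomad_af"] if "gnomad_af" in out else pd.Series(np.nan, index=out.index)
    dbsnp = out["dbsnp"] if "dbsnp" in out else pd.Series(False, index=out.index)
    categories = []
    for retained, vaf, gene, pchange, snp_flag, af in zip(
        out["retained"], out["vaf"], out["gene"], out["protein_change"],
        dbsnp, gnomad,
    ):
        if not retained:
            categories.append("filtered")
        else:
            categories.append(
                classify_call(
                    vaf,
                    gene=gene,
                    protein_change=pchange,
                    dbsnp_snp=bool(snp_flag),
                    gnomad_af=None if pd.isna(af) else float(af),
                    thresholds=thresholds,
                )
            )
    out["category"] = categories
    out["gene_class"] = [
        assign_gene_class(g, hr_genes=hr_genes, ch_genes=ch_genes)
        for g in out["gene"]
    ]
    reason = out["filter_reason"].copy()
    reason[out["category"] == "snp_excluded"] = "common_snp_high_vaf"
    out["filter_reason"] = reason
    return out


@dataclass(frozen=True)
class CHStatus:
    """Patient-level clonal-hematopoiesis call."""

    positive: bool
    max_vaf: float
    n_mutations: int


def call_ch_status(
    classified: pd.DataFrame,
    ch_gene_list,
    *,
    vaf_threshold: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> CHStatus:
    """CH status for one patient's classified variants.

    Positive when at least one somatic variant in a CH-panel gene has
    VAF >= 1% (inclusive); also reports the largest qualifying clone's VAF and
    the number of qualifying mutations.
    """
    genes = {canonical_gene(g) for g in ch_gene_list}
    if not genes:
        raise ValueError("CH gene list must not be empty")
    cut = thresholds.ch_vaf if vaf_threshold is None else vaf_threshold
    qualifying = classified[
        (classified["category"] == "somatic")
        & classified["gene"].map(canonical_gene).isin(genes)
        & (classified["vaf"] >= cut)
    ]
    max_vaf = float(qualifying["vaf"].max()) if len(qualifying) else 0.0
    return CHStatus(
        positive=bool(len(qualifying)),
        max_vaf=max_vaf,
        n_mutations=int(len(qualifying)),
    )
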