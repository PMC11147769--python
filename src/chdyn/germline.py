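"""Pathogenic germline BRCA / HR-pathway variant calling.

Rule-based, per-variant and fully offline: pathogenicity databases
(ClinVar, ENIGMA, expert review) enter as pre-annotated columns.  BRCA1/2
variants are pathogenic when any database classes them (likely) pathogenic,
or when the effect is deleterious (splice site, truncating indel, stopgain,
startloss) and the population allele frequency is below 1%.  Other
HR-pathway genes use only the deleterious-and-rare arm.  A missing
population AF counts as rare (below 1%) and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chdyn.config import DEFAULT_THRESHOLDS, Thresholds
from chdyn.genes import canonical_gene, default_hr_genes

__all__ = [
    "GermlineCall",
    "classify_brca_germline",
    "classify_hrd_germline",
    "classify_germline_table",
    "patient_hrd_status",
]

BRCA_GENES = frozenset({"BRCA1", "BRCA2"})
DELETERIOUS_EFFECTS = frozenset(
    {"splice", "truncating_indel", "stopgain", "startloss", "frameshift"}
)
PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})


@dataclass(frozen=True)
class GermlineCall:
    """Pathogenicity call for one germline variant.

    ``basis`` records the first matching rule in priority order
    clinvar > enigma > expert > deleterious_rare; ``af_assumed_rare`` is set
    when the population AF was absent and treated as < 1%.
    """

    gene: str
    pathogenic: bool
    basis: str | None = None
    af_assumed_rare: bool = False


def _norm_class(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value).strip().lower().replace(" ", "_")


def _is_deleterious(effect: str) -> bool:
    return _norm_class(effect) in DELETERIOUS_EFFECTS


def _af_is_rare(gnomad_af, cutoff: float) -> tuple[bool, bool]:
    """(is_rare, assumed) — missing AF is treated as rare, flagged assumed."""
    if gnomad_af is None or (isinstance(gnomad_af, float) and np.isnan(gnomad_af)):
        return True, True
    return float(gnomad_af) < cutoff, False


def classify_brca_germline(
    *,
    gene: str,
    effect: str,
    vaf: float,
    clinvar=None,
    enigma=None,
    expert=None,
    gnomad_af=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> GermlineCall:
    """Pathogenicity of a germline BRCA1/2 variant (VAF must exceed 40%).

    Non-BRCA genes are routed to :func:`classify_hrd_germline`.
    """
    gene = canonical_gene(gene)
    if gene not in BRCA_GENES:
        return classify_hrd_germline(
            gene=gene, effect=effect, vaf=vaf, gnomad_af=gnomad_af,
            hr_gene_list=None, thresholds=thresholds,
        )
    if vaf <= thresholds.snp_vaf:
        raise ValueError(
            f"germline classification requires VAF > {thresholds.snp_vaf}, got {vaf}"
        )
    for basis, value in (("clinvar", clinvar), ("enigma", enigma), ("expert", expert)):
        if _norm_class(value) in PATHOGENIC_CLASSES:
            return GermlineCall(gene=gene, pathogenic=True, basis=basis)
    rare, assumed = _af_is_rare(gnomad_af, thresholds.pathogenic_pop_af)
    if _is_deleterious(effect) and rare:
        return GermlineCall(
            gene=gene, pathogenic=True, basis="deleterious_rare",
            af_assumed_rare=assumed,
        )
    return GermlineCall(gene=gene, pathogenic=False)


def classify_hrd_germline(
    *,
    gene: str,
    effect: str,
    vaf: float,
    gnomad_af=None,
    hr_gene_list=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> GermlineCall:
    """Pathogenicity of a germline HR-pathway variant: deleterious and rare."""
    gene = canonical_gene(gene)
    hr = {canonical_gene(g) for g in (hr_gene_list or default_hr_genes())}
    if gene not in hr:
        return GermlineCall(gene=gene, pathogenic=False)
    if vaf <= thresholds.snp_vaf:
        raise ValueError(
            f"germline classification requires VAF > {thresholds.snp_vaf}, got {vaf}"
        )
    rare, assumed = _af_is_rare(gnomad_af, thresholds.pathogenic_pop_af)
    if _is_deleterious(effect) and rare:
        return GermlineCall(
            gene=gene, pathogenic=True, basis="deleterious_rare",
            af_assumed_rare=assumed,
        )
    return GermlineCall(gene=gene, pathogenic=False)


def classify_germline_table(
    germline: pd.DataFrame,
    *,
    hr_gene_list=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify a table of germline-range calls (adds pathogenic/basis columns).

    Expects columns gene, effect, vaf and optional clinvar / enigma / expert /
    gnomad_af.  BRCA1/2 rows use the annotation-or-deleterious rule, other
    HR-panel rows the deleterious-and-rare rule; rows outside both panels are
    non-pathogenic.
    """
    hr = list(hr_gene_list) if hr_gene_list is not None else default_hr_genes()
    out = germline.copy()
    calls = []
    for _, row in out.iterrows():
        gene = canonical_gene(row["gene"])
        kwargs = dict(
            gene=gene,
            effect=row.get("effect", ""),
            vaf=float(row["vaf"]),
            gnomad_af=row.get("gnomad_af"),
            thresholds=thresholds,
        )
        if gene in BRCA_GENES:
            call = classify_brca_germline(
                clinvar=row.get("clinvar"),
                enigma=row.get("enigma"),
                expert=row.get("expert"),
                **kwargs,
            )
        else:
            call = classify_hrd_germline(hr_gene_list=hr, **kwargs)
        calls.append(call)
    out["pathogenic"] = [c.pathogenic for c in calls]
    out["basis"] = [c.basis or "" for c in calls]
    out["af_assumed_rare"] = [c.af_assumed_rare for c in calls]
    return out


def patient_hrd_status(germline_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-patient germline-HRD status: any pathogenic BRCA or HR call.

    Input must carry patient_id and pathogenic columns (e.g. the output of
    :func:`classify_germline_table`); returns patient_id + hrd_status.
    """
    if len(germline_calls) == 0:
        return pd.DataFrame(columns=["patient_id", "hrd_status"])
    status = (
        germline_calls.groupby("patient_id")["pathogenic"]
        .any()
        .rename("hrd_status")
        .reset_index()
    )
    return status
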