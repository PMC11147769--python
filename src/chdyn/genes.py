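"""Gene classes and hotspot sites used throughout the analysis.

The CH and HR gene panels ship as editable plain-text lists under
``chdyn/data``; both can be replaced per run.  DTA and DDR membership is
fixed: DTA are the epigenetic regulators dominating ageing-related clonal
hematopoiesis, DDR the DNA-damage-response genes whose clones are selected
by cytotoxic therapy.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from pathlib import Path

DTA_GENES = frozenset({"DNMT3A", "TET2", "ASXL1"})
DDR_GENES = frozenset({"TP53", "PPM1D", "ATM", "CHEK2"})

# Legacy / alias symbols canonicalized on input (SFRS2 is the old SRSF2 symbol).
GENE_ALIASES = {"SFRS2": "SRSF2", "MLL": "KMT2A", "MRE11A": "MRE11"}

# Highly recurrent CH driver substitutions retained even when flagged as SNPs.
# Codon-level entries (site=None) match any substitution at that codon.
_HOTSPOTS: frozenset[tuple[str, int, str | None]] = frozenset(
    {
        ("DNMT3A", 882, None),
        ("GNB1", 57, "E"),
        ("JAK2", 617, "F"),
        ("SF3B1", 666, None),
        ("SF3B1", 700, None),
        ("SRSF2", 95, None),
        ("U2AF1", 34, None),
        ("U2AF1", 157, None),
    }
)

_PROTEIN_CHANGE_RE = re.compile(
    r"^(?:p\.)?([A-Za-z\*]{1,3})(\d+)([A-Za-z\*=]*)$"
)


def canonical_gene(gene: str) -> str:
    gene = str(gene).strip().upper()
    return GENE_ALIASES.get(gene, gene)


def parse_protein_change(protein_change: str) -> tuple[str, int, str] | None:
    """Split e.g. ``R882H`` / ``p.V617F`` into (ref_aa, codon, alt_aa).

    Returns None for strings that do not look like a simple substitution
    (frameshifts, multi-residue indels, empty annotation).
    """
    if protein_change is None:
        return None
    m = _PROTEIN_CHANGE_RE.match(str(protein_change).strip())
    if m is None:
        return None
    ref, codon, alt = m.groups()
    return ref.upper(), int(codon), alt.upper()


def is_hotspot(gene: str, protein_change: str) -> bool:
    """True for the recurrent CH driver sites exempt from SNP exclusion.

    DNMT3A R882, SF3B1 K666/K700, SRSF2 P95 and U2AF1 S34/Q157 match at the
    codon level (any substitution); GNB1 K57E and JAK2 V617F require the exact
    substitution.  Unparseable protein changes are treated as non-hotspot with
    a warning rather than an error.
    """
    gene = canonical_gene(gene)
    if gene not in {g for g, _, _ in _HOTSPOTS}:
        return False
    parsed = parse_protein_change(protein_change)
    if parsed is None:
        warnings.warn(
            f"unparseable protein change {protein_change!r} for {gene}; "
            "treated as non-hotspot",
            stacklevel=2,
        )
        return False
    _, codon, alt = parsed
    for g, c, site in _HOTSPOTS:
        if g == gene and c == codon and (site is None or site == alt):
            return True
    return False


def _load_packaged_list(name: str) -> list[str]:
    text = resources.files("chdyn.data").joinpath(name).read_text()
    return read_gene_list_text(text)


def read_gene_list_text(text: str) -> list[str]:
    genes = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(canonical_gene(line))
    return genes


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list ('#' comments allowed)."""
    return read_gene_list_text(Path(path).read_text())


def default_ch_genes() -> list[str]:
    """Packaged panel of genes recurrently mutated in clonal hematopoiesis."""
    return _load_packaged_list("ch_genes.txt")


def default_hr_genes() -> list[str]:
    """Packaged homologous-recombination pathway panel (editable stand-in)."""
    return _load_packaged_list("hr_genes.txt")


def assign_gene_class(gene: str, hr_genes=None, ch_genes=None) -> str:
    """Map a gene symbol to {DTA, DDR, HR, other_CH, other}.

    DTA and DDR take precedence over HR membership (ATM and CHEK2 sit in both
    the DDR set and many HR panels; the analysis groups them as DDR).
    """
    gene = canonical_gene(gene)
    if gene in DTA_GENES:
        return "DTA"
    if gene in DDR_GENES:
        return "DDR"
    hr = set(hr_genes) if hr_genes is not None else set(default_hr_genes())
    if gene in hr:
        return "HR"
    ch = set(ch_genes) if ch_genes is not None else set(default_ch_genes())
    if gene in ch:
        return "other_CH"
    return "other"
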