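"""Reading and writing the package's interchange formats.

TSV is the primary format everywhere: variant tables (one row per variant
observation per sample), truth tables, single-cell genotype matrices
(cells x variants, 0/1/2/NA) and SNP profile tables.  Variant tables can
additionally round-trip through minimal VCF 4.2 with the non-standard
annotation fields carried as INFO key=value pairs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from chdyn.synthetic import VARIANT_TABLE_COLUMNS

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "write_vcf",
    "read_vcf",
]

_DTYPES = {
    "patient_id": str,
    "sample_id": str,
    "source": str,
    "chrom": str,
    "ref": str,
    "alt": str,
    "gene": str,
    "protein_change": str,
    "effect": str,
    "clinvar": str,
    "enigma": str,
}

_INFO_FIELDS = [
    ("PATIENT", "patient_id", "String"),
    ("SAMPLE", "sample_id", "String"),
    ("SRC", "source", "String"),
    ("TP", "timepoint_years", "Float"),
    ("GENE", "gene", "String"),
    ("PCHANGE", "protein_change", "String"),
    ("EFFECT", "effect", "String"),
    ("VAF", "vaf", "Float"),
    ("ALT_READS", "alt_reads", "Integer"),
    ("DP", "depth", "Integer"),
    ("DBSNP", "dbsnp", "String"),
    ("GNOMAD_AF", "gnomad_af", "Float"),
    ("CLINVAR", "clinvar", "String"),
    ("ENIGMA", "enigma", "String"),
]


def read_variant_table(path: str | Path, *, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a variant TSV; ``column_map`` renames input columns to the schema."""
    df = pd.read_csv(path, sep="\t", dtype=_DTYPES, keep_default_na=True,
                     na_values=[""])
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("clinvar", "enigma", "protein_change"):
        if col in df:
            df[col] = df[col].fillna("")
    if "dbsnp" in df:
        df["dbsnp"] = df["dbsnp"].astype(str).str.lower().isin(["true", "1", "yes"])
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Cells x variants TSV with values 0/1/2/NA (first column = cell id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", na_rep="NA")


def _fmt_info_value(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return "T" if value else "F"
    if isinstance(value, str):
        return value.replace(";", "_").replace(" ", "_") or None
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return format(float(value), ".6g")


def write_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Emit a variant table as minimal VCF 4.2 (annotations as INFO pairs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["##fileformat=VCFv4.2", "##source=chdyn"]
    for key, _, typ in _INFO_FIELDS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={typ},Description="{key}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for _, row in df.iterrows():
        info_parts = []
        for key, col, _ in _INFO_FIELDS:
            val = _fmt_info_value(row.get(col))
            if val is not None:
                info_parts.append(f"{key}={val}")
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]), str(int(row["pos"])), ".",
                    str(row["ref"]), str(row["alt"]), ".", "PASS",
                    ";".join(info_parts) or ".",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into the table schema."""
    col_by_key = {key: (col, typ) for key, col, typ in _INFO_FIELDS}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, _, ref, alt, _, _, info = line.split("\t")[:8]
        rec = {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt}
        for part in info.split(";"):
            if "=" not in part:
                continue
            key, val = part.split("=", 1)
            if key not in col_by_key:
                continue
            col, typ = col_by_key[key]
            if key == "DBSNP":
                rec[col] = val == "T"
            elif typ == "Float":
                rec[col] = float(val)
            elif typ == "Integer":
                rec[col] = int(val)
            else:
                rec[col] = val
        rows.append(rec)
    df = pd.DataFrame(rows)
    for col in ("clinvar", "enigma", "protein_change"):
        if col not in df:
            df[col] = ""
        df[col] = df[col].fillna("")
    if "gnomad_af" not in df:
        df["gnomad_af"] = np.nan
    if "dbsnp" not in df:
        df["dbsnp"] = False
    else:
        df["dbsnp"] = df["dbsnp"].fillna(False).astype(bool)
    return df[[c for c in VARIANT_TABLE_COLUMNS if c in df.columns]]
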