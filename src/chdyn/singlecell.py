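"""Single-cell DNA genotype analysis: QC, demultiplexing, clones, exclusivity.

Input is a cells x variants genotype matrix with values 0 (wt), 1 (het),
2 (hom) and NaN (missing).  Clones are defined as groups of cells sharing an
identical genotype vector over the somatic target variants; cells missing a
genotype at any target are left unassigned rather than imputed.  A mutant
clone is reported when its mutated allele is carried by at least 5 cells, and
a sample enters analysis with at least 400 genotyped cells.  Homozygous-
mutant clones are flagged as loss of heterozygosity (LOH).

Mutual exclusivity of two mutations is assessed against the doublet-driven
background: with doublet rate d and mutant-cell fractions f_a, f_b, truly
exclusive clones still produce double-mutant barcodes at rate ~ 2 d f_a f_b;
a one-sided binomial test asks whether the observed double-mutant count
exceeds that background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from chdyn.config import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "Clone",
    "QCResult",
    "ExclusivityResult",
    "qc_sample",
    "demultiplex",
    "call_clones",
    "test_exclusivity",
    "compare_serial_architecture",
    "clone_table",
]


@dataclass(frozen=True)
class Clone:
    """A group of cells with identical somatic genotype vector."""

    label: str
    genotype: tuple[float, ...]
    cell_count: int
    fraction: float
    loh: bool


@dataclass(frozen=True)
class QCResult:
    passed: bool
    genotyped_cells: int


@dataclass(frozen=True)
class ExclusivityResult:
    verdict: str                 # 'exclusive' | 'co_occurring'
    double_mutant_cells: int
    double_mutant_fraction: float
    expected_background: float
    p_value: float
    degenerate: bool = False


def qc_sample(
    matrix: pd.DataFrame,
    *,
    somatic_variants=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> QCResult:
    """Sample QC: a cell is genotyped if it has a non-missing call at >= 1
    somatic target; the sample passes with >= 400 genotyped cells."""
    cols = list(somatic_variants) if somatic_variants is not None else list(matrix.columns)
    if len(matrix) == 0 or not cols:
        return QCResult(False, 0)
    genotyped = int(matrix[cols].notna().any(axis=1).sum())
    return QCResult(genotyped >= thresholds.min_genotyped_cells, genotyped)


def demultiplex(
    matrix: pd.DataFrame,
    sample_snp_profiles: pd.DataFrame,
    *,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Assign pooled cells to samples by germline SNP-profile concordance.

    ``sample_snp_profiles``: samples x SNPs genotype table (0/1/2).  Each cell
    goes to the profile with maximum concordance (fraction of matching calls
    over the cell's non-missing SNPs).  Cells whose best concordance is below
    0.9, whose best-vs-second margin is below 0.1, or with no usable SNP call
    are labelled 'ambiguous' (inter-sample doublets and noise).

    Returns a table: cell_id, assigned_sample, best_concordance, margin.
    """
    if len(sample_snp_profiles) < 2:
        raise ValueError("demultiplexing needs at least 2 sample profiles")
    profiles = sample_snp_profiles.loc[:, sample_snp_profiles.columns]
    dup = profiles.duplicated(keep=False)
    if dup.any():
        raise ValueError(
            f"identical SNP profiles are not separable: {list(profiles.index[dup])}"
        )
    snps = [c for c in profiles.columns if c in matrix.columns]
    if not snps:
        raise ValueError("no shared SNP markers between matrix and profiles")
    cells = matrix[snps].to_numpy(dtype=float)          # n_cells x m
    prof = profiles[snps].to_numpy(dtype=float)         # n_samples x m
    observed = ~np.isnan(cells)
    n_obs = observed.sum(axis=1)
    conc = np.zeros((cells.shape[0], prof.shape[0]))
    for j in range(prof.shape[0]):
        match = (cells == prof[j][None, :]) & observed
        with np.errstate(invalid="ignore", divide="ignore"):
            conc[:, j] = np.where(n_obs > 0, match.sum(axis=1) / n_obs, 0.0)
    order = np.argsort(conc, axis=1)
    best_idx = order[:, -1]
    best = conc[np.arange(len(cells)), best_idx]
    second = conc[np.arange(len(cells)), order[:, -2]]
    margin = best - second
    names = list(profiles.index)
    ambiguous = (
        (best < thresholds.demux_min_concordance)
        | (margin < thresholds.demux_min_margin)
        | (n_obs == 0)
    )
    assigned = [
        "ambiguous" if amb else names[i] for amb, i in zip(ambiguous, best_idx)
    ]
    return pd.DataFrame(
        {
            "cell_id": list(matrix.index),
            "assigned_sample": assigned,
            "best_concordance": best,
            "margin": margin,
        }
    )


def call_clones(
    matrix: pd.DataFrame,
    *,
    somatic_variants=None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[Clone]:
    """Group cells by exact somatic genotype vector into clones.

    Cells with a missing genotype at any somatic target are unassigned.  The
    all-wild-type group is C0; mutant groups with >= 5 cells are reported as
    C1, C2, ... ordered by descending cell count.  Fractions are of all
    genotyped (QC-counted) cells, so clone fractions plus the unassigned
    fraction sum to 1.  A clone is LOH-flagged if any target is homozygous
    mutant.
    """
    cols = list(somatic_variants) if somatic_variants is not None else list(matrix.columns)
    sub = matrix[cols]
    genotyped_mask = sub.notna().any(axis=1)
    n_genotyped = int(genotyped_mask.sum())
    if n_genotyped == 0:
        return []
    complete = sub[sub.notna().all(axis=1)]
    clones: list[Clone] = []
    groups = (
        complete.groupby(cols, sort=False).size() if len(complete) else pd.Series(dtype=int)
    )
    wt_vector = tuple(0.0 for _ in cols)
    mutant = []
    c0_count = 0
    for vec, count in groups.items():
        vec_t = tuple(float(v) for v in (vec if isinstance(vec, tuple) else (vec,)))
        if vec_t == wt_vector:
            c0_count = int(count)
        elif count >= thresholds.min_clone_cells:
            mutant.append((vec_t, int(count)))
    mutant.sort(key=lambda vc: (-vc[1], vc[0]))
    clones.append(
        Clone("C0", wt_vector, c0_count, c0_count / n_genotyped, loh=False)
    )
    for i, (vec, count) in enumerate(mutant, start=1):
        clones.append(
            Clone(
                f"C{i}", vec, count, count / n_genotyped,
                loh=any(g == 2.0 for g in vec),
            )
        )
    return clones


def clone_table(clones: list[Clone], variant_ids) -> pd.DataFrame:
    """Clone list as a tidy table (one row per clone, genotype columns)."""
    rows = []
    for c in clones:
        rec = {"clone": c.label, "cell_count": c.cell_count,
               "fraction": c.fraction, "loh": c.loh}
        rec.update(dict(zip(variant_ids, c.genotype)))
        rows.append(rec)
    return pd.DataFrame(rows)


def test_exclusivity(
    matrix: pd.DataFrame,
    variant_a: str,
    variant_b: str,
    doublet_rate: float,
    *,
    alpha: float = 0.05,
) -> ExclusivityResult:
    """Mutual exclusivity of two mutations against the doublet background.

    Uses cells genotyped at both loci.  Observed double mutants (both loci
    mutated) are compared to the expected doublet-driven count
    n * 2 * d * f_a * f_b by a one-sided binomial test; 'co_occurring' when
    the observed count significantly exceeds that background.
    """
    sub = matrix[[variant_a, variant_b]].dropna()
    a_mut = sub[variant_a] >= 1
    b_mut = sub[variant_b] >= 1
    if int(a_mut.sum()) < 5 or int(b_mut.sum()) < 5:
        raise ValueError("both variants must be mutated in >= 5 genotyped cells")
    n = len(sub)
    f_a = float(a_mut.mean())
    f_b = float(b_mut.mean())
    double = int((a_mut & b_mut).sum())
    background = min(1.0, 2.0 * doublet_rate * f_a * f_b)
    if f_a == 0.0 or f_b == 0.0:
        return ExclusivityResult(
            "exclusive", double, double / n, background, 1.0, degenerate=True
        )
    if background == 0.0:
        p = 0.0 if double > 0 else 1.0
    else:
        p = float(
            stats.binomtest(double, n, background, alternative="greater").pvalue
        )
    verdict = "co_occurring" if p < alpha else "exclusive"
    return ExclusivityResult(verdict, double, double / n, background, p)


def compare_serial_architecture(
    clones_t1: list[Clone],
    clones_t2: list[Clone],
    *,
    variant_ids_t1=None,
    variant_ids_t2=None,
) -> pd.DataFrame:
    """Match clones across two timepoints by genotype vector.

    Both samples must share the somatic variant panel (same loci, same
    order).  Returns one row per genotype seen at either timepoint with both
    fractions, the delta, and appeared/disappeared flags.
    """
    if variant_ids_t1 is not None and variant_ids_t2 is not None:
        if list(variant_ids_t1) != list(variant_ids_t2):
            raise ValueError("serial comparison requires a shared variant panel")
    by_geno_1 = {c.genotype: c for c in clones_t1}
    by_geno_2 = {c.genotype: c for c in clones_t2}
    lengths = {len(g) for g in list(by_geno_1) + list(by_geno_2)}
    if len(lengths) > 1:
        raise ValueError("serial comparison requires a shared variant panel")
    rows = []
    for geno in sorted(set(by_geno_1) | set(by_geno_2), key=lambda g: (-sum(g), g)):
        c1, c2 = by_geno_1.get(geno), by_geno_2.get(geno)
        f1 = c1.fraction if c1 else 0.0
        f2 = c2.fraction if c2 else 0.0
        rows.append(
            dict(
                genotype="/".join(str(int(g)) for g in geno),
                label_t1=c1.label if c1 else "",
                label_t2=c2.label if c2 else "",
                fraction_t1=f1,
                fraction_t2=f2,
                delta=f2 - f1,
                appeared=c1 is None,
                disappeared=c2 is None,
            )
        )
    return pd.DataFrame(rows)
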