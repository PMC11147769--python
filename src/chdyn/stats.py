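"""Cohort-level statistics.

Exact Fisher tests (2x2 via scipy; r x c by full enumeration of tables with
fixed margins, the same probability-based two-sided definition R's
``fisher.test`` uses), Wilcoxon rank-sum / signed-rank tests, a gene
co-occurrence matrix with Benjamini-Hochberg FDR and VAF-ordering fractions,
WB-cfDNA VAF concordance, and a baseline characteristics table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FisherResult",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "cooccurrence_matrix",
    "vaf_concordance",
    "baseline_table",
]


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float | None   # sample OR; None for r x c tables
    degenerate: bool = False   # zero margin: p = 1, OR undefined


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of an r x c table."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i, remaining_cols):
        if i == r - 1:
            table[i] = remaining_cols
            yield table
            return
        # enumerate row i cell by cell
        def fill_row(j, left_in_row, rem):
            if j == c - 1:
                if left_in_row <= rem[j]:
                    table[i, j] = left_in_row
                    new_rem = rem.copy()
                    new_rem[j] -= left_in_row
                    yield from fill(i + 1, new_rem)
                return
            hi = min(left_in_row, rem[j])
            for v in range(hi + 1):
                table[i, j] = v
                new_rem = rem.copy()
                new_rem[j] -= v
                yield from fill_row(j + 1, left_in_row - v, new_rem)

        yield from fill_row(0, row_sums[i], remaining_cols)

    yield from fill(0, np.asarray(col_sums, dtype=np.int64))


def _fisher_rxc(table: np.ndarray) -> float:
    """Exact probability-based two-sided p for an r x c table."""
    logp_obs = _log_table_prob(table)
    tol = 1e-7  # counts tables whose probability <= observed (within fp slack)
    total = 0.0
    for t in _enumerate_tables(table.sum(axis=1), table.sum(axis=0)):
        lp = _log_table_prob(t)
        if lp <= logp_obs + tol:
            total += np.exp(lp)
    return min(1.0, total)


def fisher_exact(table) -> FisherResult:
    """Exact Fisher test, probability-based two-sided p.

    2x2 tables use scipy and also report the sample odds ratio (inf when a
    zero cell makes it unbounded); larger tables are handled by full
    enumeration over fixed margins (practical for the small count totals of
    baseline tables).  A zero row or column margin gives p = 1 with the
    result flagged degenerate.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return FisherResult(1.0, None, degenerate=True)
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        a, b, c, d = table.ravel().astype(float)
        odds = np.inf if b * c == 0 else (a * d) / (b * c)
        return FisherResult(float(p), float(odds))
    return FisherResult(_fisher_rxc(table), None)


def wilcoxon_rank_sum(x, y, *, paired: bool = False) -> float:
    """Two-sided Wilcoxon p: rank-sum (Mann-Whitney) or signed-rank (paired).

    scipy picks the exact distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.  Degenerate cases (all
    paired differences zero, or identical pooled samples) return p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        if np.all(x == y):
            return 1.0
        return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == 1:
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(x), len(y)) <= 25) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def cooccurrence_matrix(
    mutations: pd.DataFrame,
    *,
    genes: list[str] | None = None,
    top_k: int = 5,
    min_mutations_per_patient: int = 2,
    fdr_method: str = "fdr_bh",
    patient_col: str = "patient_id",
    gene_col: str = "gene",
    vaf_col: str = "vaf",
) -> pd.DataFrame:
    """Pairwise gene co-occurrence among multi-mutated patients.

    ``mutations``: one row per somatic mutation (patient, gene, VAF).  The
    analysis restricts to patients with >= 2 mutations and, unless ``genes``
    is given, to the ``top_k`` most frequently mutated genes (by number of
    mutated patients).  Per unordered pair: a patients-by-gene-presence 2x2
    Fisher test, BH-adjusted across the pairs, plus the fraction of
    co-mutated patients in which gene_1's largest clone outsizes gene_2's.

    Returns one row per ordered pair (both directions share n/OR/p;
    ``frac_gene1_higher_vaf`` is direction-specific).
    """
    per_patient = mutations.groupby(patient_col)
    multi = per_patient.size()
    keep_patients = multi[multi >= min_mutations_per_patient].index
    sub = mutations[mutations[patient_col].isin(keep_patients)]
    if genes is None:
        by_gene = sub.groupby(gene_col)[patient_col].nunique().sort_values(
            ascending=False, kind="stable"
        )
        genes = list(by_gene.index[:top_k])
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for co-occurrence analysis")
    patients = list(sub[patient_col].unique())
    has = {
        g: set(sub.loc[sub[gene_col] == g, patient_col].unique()) for g in genes
    }
    max_vaf = sub.groupby([patient_col, gene_col])[vaf_col].max()

    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
    records = []
    for a, b in pairs:
        both = has[a] & has[b]
        n11 = len(both)
        n10 = len(has[a] - has[b])
        n01 = len(has[b] - has[a])
        n00 = len(patients) - n11 - n10 - n01
        res = fisher_exact([[n11, n10], [n01, n00]])
        if both:
            a_higher = sum(
                1 for p in both if max_vaf[(p, a)] > max_vaf[(p, b)]
            )
            frac_ab = a_higher / n11
        else:
            frac_ab = np.nan
        records.append((a, b, n11, res.odds_ratio, res.p_value, frac_ab))

    p_raw = [r[4] for r in records]
    p_adj = multipletests(p_raw, method=fdr_method)[1] if records else []
    rows = []
    for (a, b, n11, orr, p, frac_ab), padj in zip(records, p_adj):
        common = dict(n_cooccur=n11, odds_ratio=orr, p_raw=p, p_fdr=float(padj))
        rows.append(dict(gene_1=a, gene_2=b, frac_gene1_higher_vaf=frac_ab, **common))
        rows.append(
            dict(
                gene_1=b, gene_2=a,
                frac_gene1_higher_vaf=(np.nan if n11 == 0 else 1.0 - frac_ab),
                **common,
            )
        )
    return pd.DataFrame(rows)


def vaf_concordance(wb_vafs, cf_vafs) -> tuple[float, int]:
    """Pearson r between paired WB and cfDNA VAFs (variants seen in both).

    Raises on constant input (correlation undefined) or fewer than 3 pairs.
    """
    wb = np.asarray(list(wb_vafs), dtype=float)
    cf = np.asarray(list(cf_vafs), dtype=float)
    if len(wb) != len(cf):
        raise ValueError("paired VAF vectors must have equal length")
    if len(wb) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(wb == wb[0]) or np.all(cf == cf[0]):
        raise ValueError("constant VAF vector: correlation undefined")
    r = float(stats.pearsonr(wb, cf).statistic)
    return r, len(wb)


def baseline_table(
    patients: pd.DataFrame,
    ch_status: pd.Series | str,
    variables: dict[str, str],
) -> pd.DataFrame:
    """Baseline characteristics stratified by CH status.

    ``variables`` maps column name -> 'categorical' | 'numeric'.  Categorical
    variables get an exact Fisher test on the levels x status table; numeric
    variables an unpaired Wilcoxon rank-sum test with per-stratum median and
    IQR.  All-missing variables are skipped with a warning column note.
    """
    if isinstance(ch_status, str):
        status = patients[ch_status].astype(bool)
    else:
        status = ch_status.astype(bool)
    rows = []
    for var, kind in variables.items():
        col = patients[var]
        if col.isna().all():
            rows.append(dict(variable=var, kind=kind, p_value=np.nan,
                             summary_negative="", summary_positive="",
                             note="all values missing; skipped"))
            continue
        if kind == "categorical":
            tab = pd.crosstab(col, status)
            tab = tab.reindex(columns=[False, True], fill_value=0)
            # a single observed level carries no association signal
            p = 1.0 if tab.shape[0] < 2 else fisher_exact(tab.to_numpy()).p_value
            fmt = lambda s: "; ".join(f"{lvl}: {int(n)}" for lvl, n in s.items())
            rows.append(dict(
                variable=var, kind=kind, p_value=p,
                summary_negative=fmt(tab[False]),
                summary_positive=fmt(tab[True]),
                note="",
            ))
        elif kind == "numeric":
            neg = col[~status].dropna().astype(float)
            pos = col[status].dropna().astype(float)
            p = wilcoxon_rank_sum(neg, pos)
            fmt = lambda s: (
                f"{s.median():g} ({np.percentile(s, 25):g}-{np.percentile(s, 75):g})"
            )
            rows.append(dict(
                variable=var, kind=kind, p_value=p,
                summary_negative=fmt(neg), summary_positive=fmt(pos), note="",
            ))
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var}")
    return pd.DataFrame(rows)
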