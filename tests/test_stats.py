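"""Cohort statistics: exact Fisher tests, Wilcoxon, co-occurrence, baseline."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from chdyn.stats import (
    baseline_table,
    cooccurrence_matrix,
    fisher_exact,
    vaf_concordance,
    wilcoxon_rank_sum,
)
from chdyn.stats import _fisher_rxc  # enumeration path, used as dual route


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        res = fisher_exact([[0, 0], [5, 5]])
        assert res.degenerate and res.p_value == 1.0 and res.odds_ratio is None

    def test_odds_ratio_reported(self):
        res = fisher_exact([[10, 2], [3, 9]])
        assert res.odds_ratio == pytest.approx(15.0)
        assert fisher_exact([[5, 0], [3, 9]]).odds_ratio == np.inf

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 5], [7, 2]],
            [[1, 9], [11, 3]],
            [[12, 4], [5, 10]],
            [[2, 2], [2, 2]],
            [[8, 1], [2, 14]],
        ],
    )
    def test_2x2_matches_full_enumeration(self, table):
        """The scipy 2x2 path agrees with our own fixed-margin enumeration."""
        assert fisher_exact(table).p_value == pytest.approx(
            _fisher_rxc(np.asarray(table, dtype=np.int64)), rel=1e-9
        )

    def test_rxc_reduces_to_2x2(self):
        """A 3x2 table with an empty-but-consistent row matches its 2x2 core."""
        p3 = fisher_exact([[3, 5], [7, 2], [0, 0]])
        # zero row margin: degenerate by the margin rule
        assert p3.degenerate
        p_rxc = _fisher_rxc(np.array([[3, 5], [7, 2]], dtype=np.int64))
        assert fisher_exact([[3, 5], [7, 2]]).p_value == pytest.approx(p_rxc, rel=1e-9)

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3]])


class TestWilcoxon:
    def test_identical_paired(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], paired=True) == 1.0

    def test_duplicated_unpaired(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum(x, list(x)) == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_small_n(self):
        x = list(range(10))
        y = [v + 100 for v in x]
        p = wilcoxon_rank_sum(x, y)
        # exact two-sided p for complete separation at n=m=10: 2/C(20,10)
        assert p == pytest.approx(2 / 184756, rel=1e-9)
        assert p < 0.001

    def test_empty_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1, 2], [1, 2, 3], paired=True)


def mutations_table(patient_genes, vafs=None):
    rows = []
    for pid, genes in patient_genes.items():
        for g in genes:
            v = vafs.get((pid, g), 0.05) if vafs else 0.05
            rows.append(dict(patient_id=pid, gene=g, vaf=v))
    return pd.DataFrame(rows)


class TestCooccurrence:
    def test_symmetric_and_frac_complementary(self):
        data = mutations_table(
            {
                "P1": ["PPM1D", "TP53"], "P2": ["PPM1D", "TP53"],
                "P3": ["PPM1D", "TET2"], "P4": ["TP53", "TET2"],
                "P5": ["PPM1D", "TP53", "TET2"],
            },
            vafs={("P1", "PPM1D"): 0.1, ("P1", "TP53"): 0.02,
                  ("P2", "PPM1D"): 0.01, ("P2", "TP53"): 0.2,
                  ("P5", "PPM1D"): 0.3, ("P5", "TP53"): 0.05},
        )
        out = cooccurrence_matrix(data, genes=["PPM1D", "TP53", "TET2"])
        ab = out[(out["gene_1"] == "PPM1D") & (out["gene_2"] == "TP53")].iloc[0]
        ba = out[(out["gene_1"] == "TP53") & (out["gene_2"] == "PPM1D")].iloc[0]
        assert ab["n_cooccur"] == ba["n_cooccur"] == 3
        assert ab["p_raw"] == ba["p_raw"]
        assert ab["frac_gene1_higher_vaf"] + ba["frac_gene1_higher_vaf"] == (
            pytest.approx(1.0)
        )

    def test_nested_pair_unbounded_or(self):
        data = mutations_table(
            {
                "P1": ["A", "B"], "P2": ["A", "B"], "P3": ["A", "B"],
                "P4": ["A", "C"], "P5": ["A", "C"],
                "P6": ["C", "D"], "P7": ["C", "D"],
            }
        )
        out = cooccurrence_matrix(data, genes=["A", "B"])
        assert out.iloc[0]["odds_ratio"] == np.inf

    def test_planted_enrichment_recovered(self, rng):
        """A planted PPM1D-TP53 association (OR 8) is estimable at n=100."""
        from chdyn.stats import fisher_exact as fe

        ors = []
        for _ in range(200):
            n = 100
            # base rates ~0.4/0.2 with log-odds shift giving true OR = 8
            ppm1d = rng.random(n) < 0.4
            p_tp53 = np.where(ppm1d, 0.555, 0.135)  # odds 1.25 vs 0.156: OR 8
            tp53 = rng.random(n) < p_tp53
            n11 = int((ppm1d & tp53).sum()); n10 = int((ppm1d & ~tp53).sum())
            n01 = int((~ppm1d & tp53).sum()); n00 = n - n11 - n10 - n01
            res = fe([[n11, n10], [n01, n00]])
            if res.odds_ratio is not None and np.isfinite(res.odds_ratio) and res.odds_ratio > 0:
                ors.append(res.odds_ratio)
        assert 4 <= np.median(ors) <= 16

    def test_fdr_monotone(self):
        p = [0.001, 0.01, 0.02, 0.5, 0.04]
        adj = multipletests(p, method="fdr_bh")[1]
        assert (adj >= np.asarray(p)).all()
        assert (np.argsort(adj) == np.argsort(np.argsort(p)).argsort()).all() or (
            np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)
        )


class TestConcordance:
    def test_identical(self):
        r, n = vaf_concordance([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r == pytest.approx(1.0) and n == 3

    def test_anti_ordered(self):
        r, _ = vaf_concordance([0.1, 0.2, 0.3], [0.3, 0.2, 0.1])
        assert r < 0

    def test_constant_undefined(self):
        with pytest.raises(ValueError):
            vaf_concordance([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])


class TestBaselineTable:
    def patients(self):
        return pd.DataFrame(
            {
                "ch_positive": [True] * 5 + [False] * 5,
                "grade": ["a", "a", "b", "b", "a", "a", "a", "b", "b", "a"],
                "age": [70, 72, 68, 71, 69, 55, 54, 57, 52, 56],
            }
        )

    def test_identical_categorical_p1(self):
        out = baseline_table(
            self.patients(), "ch_positive", {"grade": "categorical"}
        )
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_numeric_wilcoxon(self):
        out = baseline_table(self.patients(), "ch_positive", {"age": "numeric"})
        assert out.loc[0, "p_value"] < 0.05
        assert "(" in out.loc[0, "summary_positive"]  # median (IQR) formatting

    def test_all_missing_skipped(self):
        pts = self.patients()
        pts["lab"] = np.nan
        out = baseline_table(pts, "ch_positive", {"lab": "numeric"})
        assert "skipped" in out.loc[0, "note"]

    def test_row_order_invariance(self):
        pts = self.patients()
        a = baseline_table(pts, "ch_positive", {"grade": "categorical", "age": "numeric"})
        b = baseline_table(
            pts.sample(frac=1.0, random_state=3), "ch_positive",
            {"grade": "categorical", "age": "numeric"},
        )
        assert np.allclose(a["p_value"], b["p_value"])
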