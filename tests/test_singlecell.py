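"""Single-cell QC, demultiplexing, clone calling and exclusivity."""

import numpy as np
import pandas as pd
import pytest

from chdyn.singlecell import (
    call_clones,
    compare_serial_architecture,
    demultiplex,
    qc_sample,
)
from chdyn.singlecell import test_exclusivity as exclusivity_verdict  # noqa: it is
# a library function, aliased so pytest does not collect it as a test
from chdyn.synthetic import simulate_genotype_matrix, simulate_pooled_snp_matrix


def matrix_from_groups(*groups):
    """Build a genotype matrix from (genotype_vector, n_cells) groups."""
    rows = []
    for vec, n in groups:
        rows.extend([list(vec)] * n)
    m = pd.DataFrame(rows, columns=[f"v{j}" for j in range(len(groups[0][0]))])
    m.index = [f"cell{i}" for i in range(len(m))]
    return m


class TestQC:
    def test_boundary(self):
        assert qc_sample(matrix_from_groups(((0,), 400))).passed
        assert not qc_sample(matrix_from_groups(((0,), 399))).passed

    def test_all_missing(self):
        m = matrix_from_groups(((np.nan,), 500))
        res = qc_sample(m)
        assert not res.passed and res.genotyped_cells == 0

    def test_empty(self):
        res = qc_sample(pd.DataFrame())
        assert not res.passed and res.genotyped_cells == 0

    def test_partial_genotype_counts(self):
        m = matrix_from_groups(((1, np.nan), 250), ((np.nan, np.nan), 100),
                               ((0, 0), 200))
        assert qc_sample(m).genotyped_cells == 450


class TestDemultiplex:
    def profiles(self):
        return pd.DataFrame(
            [[0, 1, 2, 0, 1, 2, 0, 1], [2, 1, 0, 2, 1, 0, 2, 1]],
            index=["sampleA", "sampleB"],
            columns=[f"snp{j}" for j in range(8)],
        )

    def test_perfect_match(self):
        prof = self.profiles()
        m = pd.DataFrame([prof.loc["sampleA"]], index=["cell0"])
        out = demultiplex(m, prof)
        assert out.loc[0, "assigned_sample"] == "sampleA"

    def test_mixed_cell_ambiguous(self):
        prof = self.profiles()
        mixed = np.maximum(prof.loc["sampleA"].to_numpy(), prof.loc["sampleB"].to_numpy())
        m = pd.DataFrame([mixed], index=["cell0"], columns=prof.columns)
        out = demultiplex(m, prof)
        assert out.loc[0, "assigned_sample"] == "ambiguous"

    def test_identical_profiles_error(self):
        prof = self.profiles()
        prof.loc["sampleB"] = prof.loc["sampleA"]
        with pytest.raises(ValueError):
            demultiplex(prof.iloc[:1], prof)

    def test_simulated_pool_accuracy(self, rng):
        """>= 95% of singlets correctly assigned at 5% doublets."""
        profiles = rng.integers(0, 3, size=(2, 16)).astype(float)
        while (profiles[0] == profiles[1]).mean() > 0.7:
            profiles = rng.integers(0, 3, size=(2, 16)).astype(float)
        prof_df = pd.DataFrame(
            profiles, index=["sampleA", "sampleB"],
            columns=[f"snp{j}" for j in range(16)],
        )
        matrix, truth = simulate_pooled_snp_matrix(
            profiles, 2000, ado_rate=0.02, doublet_rate=0.05, rng=rng,
            snp_ids=list(prof_df.columns),
        )
        out = demultiplex(matrix, prof_df)
        singlet = ~truth["is_doublet"].to_numpy()
        expected = np.where(truth["sample_1"] == 0, "sampleA", "sampleB")
        assigned = out["assigned_sample"].to_numpy()
        correct = (assigned[singlet] == expected[singlet]).mean()
        assert correct >= 0.95


class TestCallClones:
    def test_basic_two_groups(self):
        m = matrix_from_groups(((1,), 600), ((0,), 400))
        clones = call_clones(m)
        by_label = {c.label: c for c in clones}
        assert by_label["C0"].cell_count == 400
        assert by_label["C1"].cell_count == 600
        assert by_label["C1"].genotype == (1.0,)

    def test_minimum_clone_size(self):
        m = matrix_from_groups(((1,), 4), ((0,), 500))
        labels = [c.label for c in call_clones(m)]
        assert labels == ["C0"]

    def test_loh_flag(self):
        m = matrix_from_groups(((2,), 50), ((0,), 500))
        clones = {c.label: c for c in call_clones(m)}
        assert clones["C1"].loh

    def test_missing_genotype_unassigned(self):
        m = matrix_from_groups(((1, np.nan), 100), ((1, 0), 50), ((0, 0), 300))
        clones = call_clones(m)
        fractions = sum(c.fraction for c in clones)
        # 100 incomplete cells are genotyped but unassigned
        assert fractions == pytest.approx(350 / 450)

    def test_fraction_sum_invariant(self, rng):
        matrix, _ = simulate_genotype_matrix(
            [((1, 0), 0.3), ((0, 1), 0.25), ((1, 2), 0.1)], 3000, 0.05, 0.05, rng
        )
        clones = call_clones(matrix)
        complete = matrix.dropna()
        genotyped = matrix.notna().any(axis=1).sum()
        unassigned = (genotyped - len(complete)) / genotyped
        small_groups = 1 - unassigned - sum(c.fraction for c in clones)
        assert sum(c.fraction for c in clones) + unassigned + small_groups == (
            pytest.approx(1.0, abs=1e-12)
        )
        assert small_groups >= 0

    def test_order_invariance(self, rng):
        m = matrix_from_groups(((1, 0), 100), ((0, 1), 80), ((0, 0), 400))
        shuffled = m.sample(frac=1.0, random_state=5)
        reordered_cols = shuffled[list(shuffled.columns)[::-1]]
        a = call_clones(m)
        b = call_clones(shuffled)
        assert [(c.label, c.cell_count) for c in a] == [
            (c.label, c.cell_count) for c in b
        ]
        c_ = call_clones(reordered_cols)
        assert sorted(c.cell_count for c in a) == sorted(x.cell_count for x in c_)


class TestExclusivity:
    def test_clean_exclusive(self):
        m = matrix_from_groups(((1, 0), 200), ((0, 1), 200), ((0, 0), 600))
        res = exclusivity_verdict(m, "v0", "v1", doublet_rate=0.05)
        assert res.verdict == "exclusive"
        assert res.double_mutant_cells == 0

    def test_nested_subclone_co_occurring(self):
        # all v1-mutant cells also carry v0 (subclone within the v0 clone)
        m = matrix_from_groups(((1, 0), 300), ((1, 1), 100), ((0, 0), 600))
        res = exclusivity_verdict(m, "v0", "v1", doublet_rate=0.08)
        assert res.verdict == "co_occurring"
        assert res.p_value < 1e-10

    def test_minimum_cells_required(self):
        m = matrix_from_groups(((1, 0), 4), ((0, 1), 200), ((0, 0), 600))
        with pytest.raises(ValueError):
            exclusivity_verdict(m, "v0", "v1", doublet_rate=0.05)

    def test_exclusive_calibration(self, rng):
        """False co-occurrence rate stays near the nominal 5% with doublets."""
        false_calls = 0
        reps = 100
        for _ in range(reps):
            matrix, _ = simulate_genotype_matrix(
                [((1, 0), 0.3), ((0, 1), 0.3)], 1000, 0.02, 0.08, rng
            )
            res = exclusivity_verdict(matrix, "var0", "var1", doublet_rate=0.08)
            false_calls += res.verdict == "co_occurring"
        assert false_calls / reps <= 0.08


class TestSerialComparison:
    def test_identical(self):
        m = matrix_from_groups(((1,), 100), ((0,), 500))
        t1, t2 = call_clones(m), call_clones(m)
        out = compare_serial_architecture(t1, t2)
        assert (out["delta"] == 0).all()

    def test_appear_disappear(self):
        t1 = call_clones(matrix_from_groups(((1, 0), 100), ((0, 0), 500)))
        t2 = call_clones(matrix_from_groups(((0, 1), 80), ((0, 0), 500)))
        out = compare_serial_architecture(t1, t2).set_index("genotype")
        assert bool(out.loc["1/0", "disappeared"])
        assert bool(out.loc["0/1", "appeared"])

    def test_disjoint_panels_error(self):
        t1 = call_clones(matrix_from_groups(((1, 0), 100), ((0, 0), 500)))
        t2 = call_clones(matrix_from_groups(((1,), 100), ((0,), 500)))
        with pytest.raises(ValueError):
            compare_serial_architecture(t1, t2)
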