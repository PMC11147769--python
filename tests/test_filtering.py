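"""Variant retention / classification cascade and CH status."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chdyn.filtering import (
    apply_retention_filters,
    call_ch_status,
    classify_call,
    classify_calls,
)
from chdyn.genes import assign_gene_class, is_hotspot


def make_calls(rows):
    defaults = dict(
        patient_id="P1", sample_id="S1", source="WB", timepoint_years=0.0,
        chrom="chr1", ref="A", alt="G", gene="TET2", protein_change="A100T",
        effect="nonsynonymous", vaf=0.05, alt_reads=100, depth=2000,
        dbsnp=False, gnomad_af=np.nan, clinvar="", enigma="",
    )
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults, pos=1000 + i)
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


class TestRetention:
    @pytest.mark.parametrize(
        "effect,alt_reads,retained",
        [
            ("synonymous", 50, False),
            ("nonsynonymous", 9, False),
            ("nonsynonymous", 10, True),
            ("splice", 10, True),
            ("intronic", 500, False),
        ],
    )
    def test_rules(self, effect, alt_reads, retained):
        out = apply_retention_filters(
            make_calls([dict(effect=effect, alt_reads=alt_reads)])
        )
        assert bool(out.loc[0, "retained"]) is retained

    def test_reason_recorded(self):
        out = apply_retention_filters(
            make_calls([dict(effect="synonymous"), dict(alt_reads=3)])
        )
        assert out.loc[0, "filter_reason"] == "effect_not_protein_altering"
        assert out.loc[1, "filter_reason"] == "alt_reads_below_minimum"


class TestHotspots:
    @pytest.mark.parametrize(
        "gene,pchange,expected",
        [
            ("DNMT3A", "R882C", True),
            ("DNMT3A", "R882H", True),
            ("JAK2", "V617F", True),
            ("JAK2", "V617G", False),
            ("DNMT3A", "R883H", False),
            ("SF3B1", "K666N", True),
            ("SFRS2", "P95L", True),   # legacy symbol canonicalized to SRSF2
            ("U2AF1", "S34F", True),
            ("GNB1", "K57E", True),
            ("GNB1", "K57N", False),
            ("TP53", "R175H", False),
        ],
    )
    def test_sites(self, gene, pchange, expected):
        assert is_hotspot(gene, pchange) is expected

    def test_unparseable_warns(self):
        with pytest.warns(UserWarning):
            assert is_hotspot("DNMT3A", "exon23_del") is False


class TestClassify:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(vaf=0.46), "germline"),
            (dict(vaf=0.46, dbsnp_snp=True), "germline"),
            (dict(vaf=0.45), "somatic"),          # strict inequality
            (dict(vaf=0.42, gnomad_af=0.02), "snp_excluded"),
            (dict(vaf=0.42, dbsnp_snp=True), "snp_excluded"),
            (dict(vaf=0.40, dbsnp_snp=True), "somatic"),  # 40% is not > 40%
            (dict(vaf=0.42, gnomad_af=0.01), "somatic"),  # 1% is not > 1%
            (dict(vaf=0.30, dbsnp_snp=True), "somatic"),  # low-VAF never SNP
            (dict(vaf=0.42), "somatic"),
        ],
    )
    def test_rules(self, kwargs, expected):
        base = dict(gene="TET2", protein_change="A100T")
        base.update(kwargs)
        vaf = base.pop("vaf")
        assert classify_call(vaf, **base) == expected

    def test_hotspot_override(self):
        assert (
            classify_call(0.42, gene="DNMT3A", protein_change="R882H", dbsnp_snp=True)
            == "somatic"
        )
        # but the germline rule still wins above 45%
        assert (
            classify_call(0.46, gene="DNMT3A", protein_change="R882H", dbsnp_snp=True)
            == "germline"
        )

    def test_partition_every_call_one_category(self):
        df = make_calls(
            [
                dict(effect="synonymous"),
                dict(vaf=0.46),
                dict(vaf=0.42, dbsnp=True),
                dict(vaf=0.05),
                dict(alt_reads=2),
            ]
        )
        out = classify_calls(df)
        assert len(out) == len(df)
        assert set(out["category"]) <= {"filtered", "germline", "snp_excluded", "somatic"}
        assert out["category"].notna().all()

    @given(
        vaf=st.floats(0.0, 1.0),
        alt_reads=st.integers(0, 2000),
        dbsnp=st.booleans(),
        gnomad=st.one_of(st.none(), st.floats(0, 0.5)),
        effect=st.sampled_from(["nonsynonymous", "splice", "synonymous", "other"]),
    )
    def test_partition_property(self, vaf, alt_reads, dbsnp, gnomad, effect):
        """Any call lands in exactly one category, depending only on itself."""
        df = make_calls(
            [dict(vaf=vaf, alt_reads=alt_reads, dbsnp=dbsnp,
                  gnomad_af=np.nan if gnomad is None else gnomad, effect=effect)]
        )
        out = classify_calls(df)
        cat = out.loc[0, "category"]
        assert cat in {"filtered", "germline", "snp_excluded", "somatic"}
        if effect in ("synonymous", "other") or alt_reads < 10:
            assert cat == "filtered"
        elif vaf > 0.45:
            assert cat == "germline"

    def test_order_independence(self):
        df = make_calls([dict(vaf=0.46), dict(vaf=0.05), dict(vaf=0.42, dbsnp=True)])
        fwd = classify_calls(df)["category"].tolist()
        rev = classify_calls(df.iloc[::-1].reset_index(drop=True))["category"].tolist()
        assert fwd == rev[::-1]


class TestCHStatus:
    def test_threshold_inclusive(self):
        df = classify_calls(make_calls([dict(gene="PPM1D", vaf=0.01)]))
        st_ = call_ch_status(df, ["PPM1D"])
        assert st_.positive and st_.max_vaf == pytest.approx(0.01)

    def test_below_threshold_negative(self):
        df = classify_calls(make_calls([dict(gene="PPM1D", vaf=0.009)]))
        assert not call_ch_status(df, ["PPM1D"]).positive

    def test_germline_only_negative(self):
        df = classify_calls(make_calls([dict(gene="PPM1D", vaf=0.48)]))
        assert not call_ch_status(df, ["PPM1D"]).positive

    def test_counts_qualifying_mutations(self):
        df = classify_calls(
            make_calls(
                [dict(gene="PPM1D", vaf=0.03), dict(gene="TET2", vaf=0.02),
                 dict(gene="BRCA1", vaf=0.05)]
            )
        )
        st_ = call_ch_status(df, ["PPM1D", "TET2"])
        assert st_.n_mutations == 2 and st_.max_vaf == pytest.approx(0.03)

    def test_empty_gene_list(self):
        df = classify_calls(make_calls([dict()]))
        with pytest.raises(ValueError):
            call_ch_status(df, [])


class TestGeneClass:
    @pytest.mark.parametrize(
        "gene,expected",
        [("TET2", "DTA"), ("DNMT3A", "DTA"), ("PPM1D", "DDR"), ("ATM", "DDR"),
         ("BRCA2", "HR"), ("JAK2", "other_CH"), ("KRT18", "other")],
    )
    def test_classes(self, gene, expected):
        assert assign_gene_class(gene) == expected


def test_germline_recovery_on_cohort(cohort):
    """True germline variants (VAF 0.5 at ~2000x) classify germline >= 99%."""
    classified = classify_calls(cohort.variants)
    key = ["patient_id", "chrom", "pos", "ref", "alt"]
    joined = classified.merge(cohort.truth, on=key, how="left", suffixes=("", "_t"))
    germ = joined[joined["true_category"].str.startswith("germline", na=False)]
    assert len(germ) > 20
    rate = (germ["category"] == "germline").mean()
    assert rate >= 0.99
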