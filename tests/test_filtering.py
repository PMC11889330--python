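"""Qualifying-variant filter: clause semantics, boundaries, monotonicity."""

import pytest
from hypothesis import given, strategies as st

from raregene.datasets import mst1r_family_annotation, mst1r_targeted_annotations
from raregene.filtering import (
    AnnotationRecord,
    FilterConfig,
    apply_filter,
    passes_dominant_filter,
    passes_recessive_filter,
)
from raregene.io import DataError, VariantRecord


def ann(consequence="missense", maf=None, hom_maf=None, cadd=25.0, gene="G"):
    return AnnotationRecord(gene=gene, consequence=consequence, maf=maf, hom_maf=hom_maf, cadd=cadd)


class TestDominantFilter:
    @pytest.mark.parametrize(
        "a, expected",
        [
            (ann("missense", maf=None, cadd=24.4), True),  # absent and deleterious
            (ann("lof", maf=None, cadd=18.0), True),  # LoF bypasses CADD
            (ann("missense", maf=None, cadd=6.248), False),  # CADD at/below 20
            (ann("missense", maf=0.005, cadd=23.4), False),  # too common
            (ann("synonymous", maf=None, cadd=35.0), False),
            (ann("other", maf=None, cadd=35.0), False),
            (ann("missense", maf=1e-4, cadd=20.5), True),  # MAF boundary passes (<=)
            (ann("missense", maf=1.00001e-4, cadd=20.5), False),
            (ann("missense", maf=None, cadd=20.0), False),  # CADD boundary fails (strict >)
        ],
    )
    def test_clause_semantics(self, a, expected):
        assert passes_dominant_filter(a, FilterConfig()) is expected


class TestRecessiveFilter:
    def test_rare_homozygote_passes_despite_common_allele(self):
        # allele frequency 0.005 but a single homozygote in the reference
        a = mst1r_family_annotation()
        assert passes_recessive_filter(a, 2) is True
        assert passes_dominant_filter(a) is False

    def test_heterozygote_never_qualifies(self):
        assert passes_recessive_filter(mst1r_family_annotation(), 1) is False

    def test_common_homozygote_frequency_fails(self):
        a = ann("missense", maf=0.02, hom_maf=0.01, cadd=30.0)
        assert passes_recessive_filter(a, 2) is False

    def test_hom_maf_boundary_passes(self):
        a = ann("missense", maf=0.005, hom_maf=1e-4, cadd=23.4)
        assert passes_recessive_filter(a, 2) is True

    def test_missing_dosage_is_an_error(self):
        with pytest.raises(DataError, match="MISSING"):
            passes_recessive_filter(ann(), None)


def _variants(annotations):
    out = []
    for i, vid in enumerate(annotations):
        chrom, pos, ref, alt = vid.split(":")
        out.append(VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt))
    return out


class TestApplyFilter:
    def test_published_targeted_rows_pass_eight_of_nine(self):
        """The nine targeted-sequencing variants: eight qualify, the CADD 6.248
        missense is excluded with an explicit reason, not silently dropped."""
        anns = {
            f"3:{i + 1}:A:G": a
            for i, a in enumerate(mst1r_targeted_annotations().values())
        }
        res = apply_filter(_variants(anns), anns, None, "dominant", FilterConfig())
        assert len(res.qualifying) == 8
        assert len(res.excluded) == 1
        assert res.excluded[0].reason == "cadd_at_or_below_threshold"

    def test_empty_and_all_synonymous_inputs_yield_nothing(self):
        assert apply_filter([], {}, None, "dominant", FilterConfig()).qualifying == []
        anns = {f"1:{i}:A:G": ann("synonymous") for i in range(1, 4)}
        res = apply_filter(_variants(anns), anns, None, "dominant", FilterConfig())
        assert res.qualifying == []
        assert all(e.reason == "not_missense_or_lof" for e in res.excluded)

    def test_missing_annotation_is_reported_not_dropped(self):
        v = [VariantRecord("1", 5, "A", "G")]
        res = apply_filter(v, {}, None, "dominant", FilterConfig())
        assert res.qualifying == []
        assert res.excluded[0].reason == "missing_annotation"

    def test_idempotent_and_order_invariant(self):
        anns = {
            "1:10:A:G": ann("missense", maf=None, cadd=30.0),
            "1:20:A:G": ann("lof", cadd=5.0),
            "1:30:A:G": ann("missense", maf=0.01, cadd=30.0),
        }
        variants = _variants(anns)
        res1 = apply_filter(variants, anns, None, "dominant", FilterConfig())
        res2 = apply_filter(list(reversed(variants)), anns, None, "dominant", FilterConfig())
        assert res1.qualifying == res2.qualifying
        kept = [v for v in variants if v.variant_id in res1.qualifying_ids]
        res3 = apply_filter(kept, anns, None, "dominant", FilterConfig())
        assert res3.qualifying == res1.qualifying


freq_st = st.one_of(st.none(), st.floats(0, 0.05, allow_nan=False))
ann_st = st.builds(
    lambda cons, maf, hom_frac, cadd: AnnotationRecord(
        gene="G",
        consequence=cons,
        maf=maf,
        hom_maf=None if maf is None else maf * hom_frac,
        cadd=cadd,
    ),
    st.sampled_from(["lof", "missense", "synonymous", "other"]),
    freq_st,
    st.floats(0, 1, allow_nan=False),
    st.floats(0, 50, allow_nan=False),
)


class TestFilterProperties:
    @given(ann_st, st.floats(0, 2e-4), st.floats(10, 30))
    def test_tightening_thresholds_never_adds_variants(self, a, maf_thr, cadd_thr):
        base = FilterConfig()
        tighter = FilterConfig(
            maf_threshold=min(maf_thr, base.maf_threshold),
            cadd_threshold=max(cadd_thr, base.cadd_threshold),
        )
        if passes_dominant_filter(a, tighter):
            assert passes_dominant_filter(a, base)

    @given(st.lists(ann_st, max_size=12))
    def test_apply_filter_matches_predicate_comprehension(self, ann_list):
        anns = {f"1:{i + 1}:A:G": a for i, a in enumerate(ann_list)}
        res = apply_filter(_variants(anns), anns, None, "dominant", FilterConfig())
        expected = {vid for vid, a in anns.items() if passes_dominant_filter(a, FilterConfig())}
        assert set(res.qualifying_ids) == expected
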