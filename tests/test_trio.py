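"""Trio inheritance classification and family candidate prioritization."""

import itertools

import pytest

from raregene.filtering import AnnotationRecord, FilterConfig
from raregene.io import DataError, GenotypeMatrix, Pedigree, PedMember, read_ped, read_vcf, read_annotation_table
from raregene.simulate import SimConfig, make_site_panel, simulate_trio
from raregene.trio import classify_inheritance, find_compound_hets, prioritize_trio

import pandas as pd


class TestClassifyInheritance:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((2, 1, 1), "homozygous_recessive"),
            ((1, 0, 0), "de_novo"),
            ((2, 0, 0), "de_novo"),
            ((1, 1, 0), "inherited_het"),
            ((1, 0, 1), "inherited_het"),
            ((1, 1, 1), "inherited_het"),
            ((2, 1, 0), "unresolved"),  # Mendelian inconsistency
            ((0, 1, 1), "unresolved"),  # proband lacks the allele
            ((None, 1, 1), "unresolved"),
            ((2, None, 1), "unresolved"),
        ],
    )
    def test_named_patterns(self, triple, expected):
        assert classify_inheritance(*triple) == expected

    def test_all_27_dosage_triples_satisfy_their_definitions(self):
        """Mendelian consistency: every non-unresolved call matches its dosage
        definition exactly, enumerated over the full diploid domain."""
        for p, f, m in itertools.product((0, 1, 2), repeat=3):
            pattern = classify_inheritance(p, f, m)
            if pattern == "de_novo":
                assert p >= 1 and f == 0 and m == 0
            elif pattern == "homozygous_recessive":
                assert p == 2 and f >= 1 and m >= 1
            elif pattern == "inherited_het":
                assert p == 1 and (f >= 1 or m >= 1)
            else:
                assert pattern == "unresolved"

    def test_missing_always_unresolved(self):
        for p, f, m in itertools.product((0, 1, 2, None), repeat=3):
            if None in (p, f, m):
                assert classify_inheritance(p, f, m) == "unresolved"


def _trio_matrix(dosages):
    """dosages: {variant_id: (proband, father, mother)}"""
    df = pd.DataFrame(
        {s: [dosages[v][i] for v in dosages] for i, s in enumerate(("P", "F", "M"))},
        index=list(dosages),
    )
    return GenotypeMatrix(df)


def _trio_pedigree():
    members = [
        PedMember("F", None, None, "male", "unaffected"),
        PedMember("M", None, None, "female", "unaffected"),
        PedMember("P", "F", "M", "unknown", "affected"),
    ]
    return Pedigree(members).trios[0]


class TestCompoundHets:
    def test_trans_pair_called_cis_not(self):
        trio = _trio_pedigree()
        gt = _trio_matrix({"v1": (1, 1, 0), "v2": (1, 0, 1)})
        assert find_compound_hets({"G": ["v1", "v2"]}, gt, trio) == [("v1", "v2")]
        gt_cis = _trio_matrix({"v1": (1, 1, 0), "v2": (1, 1, 0)})
        assert find_compound_hets({"G": ["v1", "v2"]}, gt_cis, trio) == []

    def test_ambiguous_origin_never_paired(self):
        trio = _trio_pedigree()
        gt = _trio_matrix({"v1": (1, 1, 1), "v2": (1, 0, 1)})
        assert find_compound_hets({"G": ["v1", "v2"]}, gt, trio) == []

    def test_three_trans_hets_enumerate_all_pairs(self):
        """One paternal + two maternal hets yield exactly the pairs a brute-force
        enumeration over parental-origin assignments produces."""
        trio = _trio_pedigree()
        dosages = {"v1": (1, 1, 0), "v2": (1, 0, 1), "v3": (1, 0, 1)}
        gt = _trio_matrix(dosages)
        # brute force: every (paternal-only, maternal-only) combination
        pat = [v for v, (p, f, m) in dosages.items() if p == 1 and f >= 1 and m == 0]
        mat = [v for v, (p, f, m) in dosages.items() if p == 1 and m >= 1 and f == 0]
        expected = sorted(tuple(sorted(pair)) for pair in itertools.product(pat, mat))
        assert find_compound_hets({"G": list(dosages)}, gt, trio) == expected


class TestPrioritizeTrio:
    def test_shared_recessive_candidate_flagged_segregating(self, family_files):
        variants, genotypes = read_vcf(family_files["vcf"])
        annotations = read_annotation_table(family_files["ann"])
        pedigree = read_ped(family_files["ped"])
        report = prioritize_trio(variants, annotations, genotypes, pedigree, FilterConfig())
        assert report.candidate_ids == ["3:49920100:T:G"]
        assert {c.pattern for c in report.candidates} == {"homozygous_recessive"}
        assert all(c.segregating for c in report.candidates)
        assert {c.proband_id for c in report.candidates} == {"PROBAND", "SISTER"}

    def test_low_cadd_recessive_fails_deleteriousness(self, family_files):
        variants, genotypes = read_vcf(family_files["vcf"])
        pedigree = read_ped(family_files["ped"])
        annotations = {
            "3:49920100:T:G": AnnotationRecord(
                gene="MST1R", consequence="missense", maf=0.005, hom_maf=1e-4, cadd=15.0
            )
        }
        report = prioritize_trio(variants, annotations, genotypes, pedigree, FilterConfig())
        assert report.candidates == []
        assert any(e.reason == "cadd_at_or_below_threshold" for e in report.excluded)

    def test_no_affected_proband_is_an_error(self, family_files):
        variants, genotypes = read_vcf(family_files["vcf"])
        ped = Pedigree([PedMember("X", None, None, "male", "unaffected")])
        with pytest.raises(DataError, match="affected"):
            prioritize_trio(variants, {}, genotypes, ped, FilterConfig())

    def test_candidate_set_independent_of_variant_order(self, family_files):
        variants, genotypes = read_vcf(family_files["vcf"])
        annotations = read_annotation_table(family_files["ann"])
        pedigree = read_ped(family_files["ped"])
        fwd = prioritize_trio(variants, annotations, genotypes, pedigree)
        rev = prioritize_trio(list(reversed(variants)), annotations, genotypes, pedigree)
        assert fwd.candidate_ids == rev.candidate_ids

    def test_planted_recessive_recovered_on_synthetic_trio(self):
        """A 60-site seeded synthetic trio: the planted variant (and nothing
        that truth says should fail the filter) is returned."""
        cfg = SimConfig(seed=42)
        panel = make_site_panel(cfg)
        records, genotypes, pedigree, truth = simulate_trio(panel, cfg)
        planted = next(t.variant_id for t in truth if t.planted)
        report = prioritize_trio(records, panel.annotations, genotypes, pedigree)
        assert planted in report.candidate_ids
        qualifying_truth = {t.variant_id for t in truth if t.qualifying}
        assert set(report.candidate_ids) <= qualifying_truth
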