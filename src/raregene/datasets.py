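"""Published example data: the MST1R / Tetralogy of Fallot case study.

The study reported a recessive homozygous MST1R missense variant shared by
two affected siblings (heterozygous unaffected parents), nine qualifying
heterozygous MST1R variants from targeted sequencing of 417 cases, and a
gene-burden comparison against the gnomAD v2 East Asian exome panel
(19,960 individuals, 50 qualifying alleles).  The per-variant annotations,
ACMG evidence sets and burden counts printed in that report are embedded
here as inputs for worked examples and regression tests.
"""

from __future__ import annotations

import pandas as pd

from .acmg import AcmgEvidence
from .filtering import AnnotationRecord

__all__ = [
    "mst1r_variant_table",
    "mst1r_targeted_annotations",
    "mst1r_family_annotation",
    "mst1r_burden_counts",
]

# patient, label, consequence, maf, hom_maf, cadd, acmg codes, published class
# frequency None = not observed in the reference (printed "-" / "N/A")
_ROWS = [
    ("1171", "c.2009T>G:p.V670G", "homozygous", "missense", 0.005, 1e-4, 23.4,
     "PS1, PM2, PP1, PP3", "likely_pathogenic"),
    ("1171_sister", "c.2009T>G:p.V670G", "homozygous", "missense", 0.005, 1e-4, 23.4,
     "PS1, PM2, PP1, PP3", "likely_pathogenic"),
    ("B273", "c.6G>T:p.Glu2Asp", "heterozygous", "missense", None, None, 23.6,
     "PM2, PP2, PP3", "vus"),
    ("B894", "c.745T>C:p.Tyr249His", "heterozygous", "missense", None, None, 24.4,
     "PM1, PM2, PP2, PP3", "likely_pathogenic"),
    ("B247", "c.1253C>T:p.Pro418Leu", "heterozygous", "missense", None, None, 32.0,
     "PM1, PM2, PP2, PP3", "likely_pathogenic"),
    ("NO_0178", "c.1294A>T:p.Ser432Cys", "heterozygous", "missense", None, None, 23.2,
     "PM1, PM2, PP2, PP3", "likely_pathogenic"),
    ("NO_0265", "c.1319A>G:p.Asn440Ser", "heterozygous", "missense", 0.0, 0.0, 24.8,
     "PP3", "vus"),
    ("A2076", "c.1838A>C:p.Gln613Pro", "heterozygous", "missense", 5e-5, 0.0, 24.2,
     "PP3", "vus"),
    ("NO_0357", "c.2168A>G:p.Glu723Gly", "heterozygous", "missense", None, None, 21.2,
     "PM2, PP2, PP3", "vus"),
    ("B684", "c.2759delC:p.Pro920fs", "heterozygous", "lof", None, None, 18.0,
     "PM2, PM4, PP3", "vus"),
    ("B111", "c.4105C>A:p.His1369Asn", "heterozygous", "missense", None, None, 6.248,
     "PM2, PP2", "vus"),
]

_COLUMNS = [
    "patient", "label", "zygosity", "consequence", "maf", "hom_maf", "cadd",
    "acmg_codes", "published_class",
]


def mst1r_variant_table() -> pd.DataFrame:
    """All eleven published MST1R variant rows (2 family + 9 targeted)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def _annotation(row) -> AnnotationRecord:
    def _freq(v):
        return None if v is None or pd.isna(v) else float(v)

    return AnnotationRecord(
        gene="MST1R",
        consequence=row.consequence,
        maf=_freq(row.maf),
        hom_maf=_freq(row.hom_maf),
        cadd=row.cadd,
    )


def mst1r_targeted_annotations() -> dict[str, AnnotationRecord]:
    """The nine targeted-sequencing variants, keyed by patient id."""
    df = mst1r_variant_table()
    return {
        row.patient: _annotation(row)
        for row in df.itertuples()
        if row.zygosity == "heterozygous"
    }


def mst1r_family_annotation() -> AnnotationRecord:
    """The family's recessive homozygous missense variant (p.V670G)."""
    return _annotation(next(mst1r_variant_table().itertuples()))


def mst1r_evidence_sets() -> list[tuple[str, AcmgEvidence]]:
    """(patient, ACMG evidence) pairs for all eleven rows."""
    return [
        (row.patient, AcmgEvidence.from_string(row.acmg_codes))
        for row in mst1r_variant_table().itertuples()
    ]


def mst1r_burden_counts() -> dict[str, int]:
    """Published burden-comparison counts.

    Nine qualifying alleles among 417 diploid cases (834 alleles); fifty
    qualifying alleles in the 19,960-individual reference panel.
    """
    return {
        "case_qualifying": 9,
        "n_cases": 417,
        "case_alleles": 834,
        "control_qualifying": 50,
        "n_reference": 19_960,
    }
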