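"""Readers and writers for the standard files the pipeline touches.

Covers multi-sample VCF (genotypes only), 6-column PED pedigrees,
tab-delimited per-variant annotation tables, and gnomAD-style reference
site tables.  All genomic coordinates are 1-based throughout; multi-allelic
VCF rows are decomposed into biallelic records at read time so that every
downstream count is defined per alternate allele.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "PedMember",
    "Pedigree",
    "Trio",
    "ReferenceSite",
    "ReferenceSiteTable",
    "DataError",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_annotation_table",
    "write_annotation_table",
    "read_reference_table",
    "write_reference_table",
    "MISSING",
]

#: Sentinel for a missing diploid genotype (VCF ``./.``).
MISSING = None

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class VcfParseError(DataError):
    """A VCF file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant site.

    ``variant_id`` is the canonical join key ``chrom:pos:ref:alt`` used by
    the annotation and reference tables; HGVS labels, when present, are
    carried as opaque strings.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES


class GenotypeMatrix:
    """Dosage matrix (variant_id x sample) with missing genotypes as ``pd.NA``.

    Dosage is the alternate-allele count in {0, 1, 2}; ``MISSING`` (``None``)
    exactly when the VCF genotype was ``./.``.
    """

    def __init__(self, dosages: pd.DataFrame):
        self.dosages = dosages.astype("Int8")

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.index)

    def dosage(self, variant_id: str, sample: str) -> int | None:
        v = self.dosages.at[variant_id, sample]
        return None if pd.isna(v) else int(v)

    def sample_dosages(self, variant_id: str) -> dict[str, int | None]:
        row = self.dosages.loc[variant_id]
        return {s: (None if pd.isna(v) else int(v)) for s, v in row.items()}

    def allele_count(self, variant_id: str) -> int:
        """Total alternate-allele count over non-missing samples."""
        return int(self.dosages.loc[variant_id].sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenotypeMatrix) and self.dosages.equals(other.dosages)


@dataclass(frozen=True)
class PedMember:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    affected: str  # "affected" | "unaffected" | "unknown"
    family_id: str = "0"


@dataclass(frozen=True)
class Trio:
    proband: PedMember
    father: PedMember
    mother: PedMember


@dataclass
class Pedigree:
    members: list[PedMember]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise DataError(f"duplicate sample id(s) in pedigree: {sorted(dup)}")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise DataError(
                        f"parent id {pid!r} of sample {m.sample_id!r} is not in the pedigree"
                    )

    def __getitem__(self, sample_id: str) -> PedMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def trios(self) -> list[Trio]:
        """Every member with both parents present, as a proband-centred trio."""
        out = []
        for m in self.members:
            if m.father_id is not None and m.mother_id is not None:
                out.append(Trio(m, self[m.father_id], self[m.mother_id]))
        return out

    def affected_siblings(self, proband: PedMember) -> list[PedMember]:
        """Affected members sharing both parents with ``proband`` (inclusive)."""
        return [
            m
            for m in self.members
            if m.affected == "affected"
            and m.father_id == proband.father_id
            and m.mother_id == proband.mother_id
            and m.father_id is not None
        ]


@dataclass(frozen=True)
class ReferenceSite:
    """Per-site allele bookkeeping for the reference population."""

    allele_count: int
    allele_number: int
    homozygote_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.allele_count <= self.allele_number):
            raise DataError(
                f"allele_count {self.allele_count} not in [0, allele_number={self.allele_number}]"
            )
        if 2 * self.homozygote_count > self.allele_count:
            raise DataError("homozygote_count inconsistent with allele_count")

    @property
    def maf(self) -> float:
        return self.allele_count / self.allele_number if self.allele_number else 0.0

    @property
    def hom_frequency(self) -> float:
        n_ind = self.allele_number / 2
        return self.homozygote_count / n_ind if n_ind else 0.0


class ReferenceSiteTable(dict):
    """Mapping variant_id -> ReferenceSite for a reference panel."""

    def total_qualifying_alleles(self, variant_ids: Iterable[str]) -> int:
        return sum(self[v].allele_count for v in variant_ids if v in self)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _validate_vcf_lines(path: str) -> list[str]:
    """Cheap structural pass so parse errors can name a line number."""
    samples: list[str] = []
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise VcfParseError(
                        f"{path}: line {lineno}: #CHROM header lacks FORMAT/sample columns"
                    )
                samples = cols[9:]
                saw_header = True
                continue
            if not saw_header:
                raise VcfParseError(f"{path}: line {lineno}: data before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise VcfParseError(
                    f"{path}: line {lineno}: expected {9 + len(samples)} columns, found {len(cols)}"
                )
            try:
                int(cols[1])
            except ValueError:
                raise VcfParseError(
                    f"{path}: line {lineno}: POS {cols[1]!r} is not an integer"
                ) from None
            if not cols[8].split(":")[0] == "GT":
                raise VcfParseError(
                    f"{path}: line {lineno}: FORMAT must lead with GT, found {cols[8]!r}"
                )
    if not saw_header:
        raise VcfParseError(f"{path}: no #CHROM header line found")
    return samples


def read_vcf(path: str) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a multi-sample VCF, decomposing multi-allelic rows.

    Every ALT allele of every row becomes one :class:`VariantRecord`; the
    per-sample dosage of a decomposed record counts occurrences of that
    specific alternate allele in the diploid genotype, so decomposition
    conserves total allele counts at the site.
    """
    import cyvcf2

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    samples = _validate_vcf_lines(path)

    try:
        reader = cyvcf2.VCF(path)
    except Exception as exc:  # htslib-level failure
        raise VcfParseError(f"{path}: {exc}") from exc
    if list(reader.samples) != samples:
        raise VcfParseError(f"{path}: sample columns disagree with #CHROM header")

    records: list[VariantRecord] = []
    rows: list[list[object]] = []
    seen: set[str] = set()
    for var in reader:
        genos = var.genotypes  # [allele0, allele1, phased] per sample
        for s_idx, g in enumerate(genos):
            if len(g) != 3:
                raise DataError(
                    f"{path}: non-diploid genotype for sample {samples[s_idx]!r} "
                    f"at {var.CHROM}:{var.POS}"
                )
        for alt_idx, alt in enumerate(var.ALT, start=1):
            rec = VariantRecord(chrom=str(var.CHROM), pos=int(var.POS), ref=var.REF, alt=alt)
            if rec.variant_id in seen:
                raise DataError(f"{path}: duplicate variant {rec.variant_id}")
            seen.add(rec.variant_id)
            dosages: list[object] = []
            for g in genos:
                a0, a1 = g[0], g[1]
                if a0 < 0 or a1 < 0:
                    dosages.append(pd.NA)
                else:
                    dosages.append(int(a0 == alt_idx) + int(a1 == alt_idx))
            records.append(rec)
            rows.append(dosages)
    reader.close()

    dosage_df = pd.DataFrame(
        rows, index=[r.variant_id for r in records], columns=samples, dtype="object"
    )
    return records, GenotypeMatrix(dosage_df)


def write_vcf(
    path: str,
    records: list[VariantRecord],
    genotypes: GenotypeMatrix,
    *,
    source: str = "raregene",
) -> None:
    """Write biallelic records and dosages as a minimal VCF v4.2."""
    samples = genotypes.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({r.chrom for r in records}, key=_chrom_key):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for rec in sorted(records, key=lambda r: (_chrom_key(r.chrom), r.pos, r.alt)):
            row = genotypes.dosages.loc[rec.variant_id]
            gts = []
            for s in samples:
                d = row[s]
                gts.append("./." if pd.isna(d) else {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female"}
_AFFECTED = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}


def read_ped(path: str) -> Pedigree:
    """Read a whitespace-delimited 6-column PED file."""
    members: list[PedMember] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise DataError(
                    f"{path}: line {lineno}: PED requires 6 columns, found {len(cols)}"
                )
            fam, sid, fid, mid, sex, pheno = cols
            if pheno not in _AFFECTED:
                raise DataError(
                    f"{path}: line {lineno}: phenotype code {pheno!r} not in "
                    f"{sorted(_AFFECTED)}"
                )
            members.append(
                PedMember(
                    sample_id=sid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX.get(sex, "unknown"),
                    affected=_AFFECTED[pheno],
                    family_id=fam,
                )
            )
    return Pedigree(members)


def write_ped(path: str, pedigree: Pedigree) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for m in pedigree.members:
            fh.write(
                "\t".join(
                    [
                        m.family_id,
                        m.sample_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        sex_code[m.sex],
                        aff_code[m.affected],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["variant_id", "gene", "consequence", "maf", "hom_maf", "cadd"]
_ABSENT_TOKENS = {"", "-", "N/A", "NA", "."}


def read_annotation_table(path: str):
    """Read the tab-delimited per-variant annotation table.

    Columns: variant_id, gene, consequence, maf, hom_maf, cadd.  Empty (or
    "-"/"N/A") frequency cells parse to ABSENT (``None``), which is distinct
    from an observed frequency of 0: both satisfy a rarity clause, but they
    are different facts about the reference population.
    """
    from .filtering import AnnotationRecord, CONSEQUENCE_CLASSES

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: annotation table missing columns {missing_cols}")

    out: dict[str, AnnotationRecord] = {}
    for i, row in df.iterrows():
        vid = row["variant_id"]
        cons = row["consequence"].strip()
        if cons not in CONSEQUENCE_CLASSES:
            raise DataError(
                f"{path}: row {i + 2}: unknown consequence {cons!r}; "
                f"allowed: {sorted(CONSEQUENCE_CLASSES)}"
            )
        maf = _parse_freq(row["maf"], path, i, "maf")
        hom_maf = _parse_freq(row["hom_maf"], path, i, "hom_maf")
        try:
            cadd = float(row["cadd"])
        except ValueError:
            raise DataError(
                f"{path}: row {i + 2}: cadd {row['cadd']!r} is not a number"
            ) from None
        out[vid] = AnnotationRecord(
            gene=row["gene"], consequence=cons, maf=maf, hom_maf=hom_maf, cadd=cadd
        )
    return out


def _parse_freq(cell: str, path: str, i: int, name: str) -> float | None:
    cell = cell.strip()
    if cell in _ABSENT_TOKENS:
        return None
    try:
        x = float(cell)
    except ValueError:
        raise DataError(f"{path}: row {i + 2}: {name} {cell!r} is not a number") from None
    if x < 0 or x > 1:
        raise DataError(f"{path}: row {i + 2}: {name}={x} outside [0, 1]")
    return x


def write_annotation_table(path: str, annotations: Mapping[str, "AnnotationRecord"]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for vid in annotations:
            a = annotations[vid]
            fh.write(
                "\t".join(
                    [
                        vid,
                        a.gene,
                        a.consequence,
                        "" if a.maf is None else repr(a.maf),
                        "" if a.hom_maf is None else repr(a.hom_maf),
                        repr(a.cadd),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Reference site table
# ---------------------------------------------------------------------------

REFERENCE_COLUMNS = ["variant_id", "allele_count", "allele_number", "homozygote_count"]


def read_reference_table(path: str) -> ReferenceSiteTable:
    """Read a gnomAD-style reference site table (tab-delimited counts).

    Optional ``maf`` / ``hom_frequency`` columns are recomputed from the
    counts; a mismatch beyond rounding is an error rather than a silent
    preference for one of two contradictory facts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: reference table missing columns {missing_cols}")
    table = ReferenceSiteTable()
    for i, row in df.iterrows():
        site = ReferenceSite(
            allele_count=int(row["allele_count"]),
            allele_number=int(row["allele_number"]),
            homozygote_count=int(row["homozygote_count"]),
        )
        if "maf" in df.columns and row["maf"].strip() not in _ABSENT_TOKENS:
            stated = float(row["maf"])
            if not math.isclose(stated, site.maf, rel_tol=0.05, abs_tol=5e-5):
                raise DataError(
                    f"{path}: row {i + 2}: stated maf {stated} disagrees with "
                    f"allele_count/allele_number = {site.maf:.6g}"
                )
        table[row["variant_id"]] = site
    return table


def write_reference_table(path: str, table: ReferenceSiteTable) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REFERENCE_COLUMNS + ["maf", "hom_frequency"]) + "\n")
        for vid, s in table.items():
            fh.write(
                f"{vid}\t{s.allele_count}\t{s.allele_number}\t{s.homozygote_count}"
                f"\t{s.maf:.8g}\t{s.hom_frequency:.8g}\n"
            )
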