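"""Inheritance-pattern classification within parent-offspring trios and
family candidate prioritization.

The discovery logic is classify-then-filter: each proband variant is first
labelled by inheritance pattern from the trio genotypes, then rare
deleterious candidates are retained — dominant-model candidates (de novo or
inherited heterozygous) through the dominant filter, recessive candidates
(homozygous, or compound heterozygous pairs) through the recessive or
per-het dominant filter.  Candidates carried by every affected sibling are
flagged as segregating, the observation underlying co-segregation evidence
(ACMG PP1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .filtering import (
    AnnotationRecord,
    FilterConfig,
    ExcludedVariant,
    exclusion_reason,
    passes_dominant_filter,
    passes_recessive_filter,
)
from .io import DataError, GenotypeMatrix, Pedigree, Trio, VariantRecord

__all__ = [
    "PATTERNS",
    "InheritanceCall",
    "Candidate",
    "TrioReport",
    "classify_inheritance",
    "find_compound_hets",
    "prioritize_trio",
]

PATTERNS = (
    "de_novo",
    "homozygous_recessive",
    "compound_het",
    "inherited_het",
    "unresolved",
)


@dataclass(frozen=True)
class InheritanceCall:
    variant_id: str
    proband_id: str
    pattern: str
    partner_variant_id: str | None = None  # compound_het only


def classify_inheritance(
    proband: int | None, father: int | None, mother: int | None
) -> str:
    """Label a dosage triple (proband, father, mother) at an autosomal site.

    Total over the dosage domain including MISSING (``None``):

    * any MISSING dosage, a proband without the allele, or a
      Mendelian-inconsistent combination (e.g. homozygous proband with a
      non-carrier parent) -> ``unresolved``
    * proband carries the allele, both parents dosage 0 -> ``de_novo``
    * proband homozygous, both parents carriers -> ``homozygous_recessive``
      (canonically (2, 1, 1): heterozygous unaffected parents)
    * proband heterozygous with >= 1 carrier parent -> ``inherited_het``
    """
    if proband is None or father is None or mother is None:
        return "unresolved"
    for d in (proband, father, mother):
        if d not in (0, 1, 2):
            raise DataError(f"dosage must be 0, 1, 2 or MISSING, got {d}")
    if proband == 0:
        return "unresolved"
    if father == 0 and mother == 0:
        return "de_novo"
    if proband == 2:
        if father >= 1 and mother >= 1:
            return "homozygous_recessive"
        return "unresolved"  # hom proband with a non-carrier parent
    # proband == 1, at least one carrier parent
    return "inherited_het"


def find_compound_hets(
    gene_variants: Mapping[str, Sequence[str]],
    genotypes: GenotypeMatrix,
    trio: Trio,
) -> list[tuple[str, str]]:
    """Enumerate trans-configured heterozygous pairs per gene for a trio.

    A pair qualifies iff both variants are proband-heterozygous in the same
    gene and their parental origins are unambiguous and opposite: one
    carried only by the father, the other only by the mother.  Variants
    whose origin is ambiguous (both parents carriers, or neither) are never
    paired — no statistical phasing is attempted.
    """
    pairs: list[tuple[str, str]] = []
    for gene in sorted(gene_variants):
        paternal: list[str] = []
        maternal: list[str] = []
        for vid in gene_variants[gene]:
            p = genotypes.dosage(vid, trio.proband.sample_id)
            f = genotypes.dosage(vid, trio.father.sample_id)
            m = genotypes.dosage(vid, trio.mother.sample_id)
            if p != 1 or f is None or m is None:
                continue
            if f >= 1 and m == 0:
                paternal.append(vid)
            elif m >= 1 and f == 0:
                maternal.append(vid)
        for pv in paternal:
            for mv in maternal:
                pairs.append(tuple(sorted((pv, mv))))
    return sorted(set(pairs))


@dataclass(frozen=True)
class Candidate:
    variant_id: str
    gene: str
    proband_id: str
    pattern: str
    segregating: bool
    filter_clause: str  # which model's filter the candidate passed
    partner_variant_id: str | None = None


@dataclass
class TrioReport:
    candidates: list[Candidate]
    calls: list[InheritanceCall]
    excluded: list[ExcludedVariant]

    @property
    def candidate_ids(self) -> list[str]:
        return sorted({c.variant_id for c in self.candidates})


def _call_pattern(genotypes: GenotypeMatrix, vid: str, trio: Trio, autosomal: bool) -> str:
    if not autosomal:
        return "unresolved"
    return classify_inheritance(
        genotypes.dosage(vid, trio.proband.sample_id),
        genotypes.dosage(vid, trio.father.sample_id),
        genotypes.dosage(vid, trio.mother.sample_id),
    )


def prioritize_trio(
    variants: Sequence[VariantRecord],
    annotations: Mapping[str, AnnotationRecord],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: FilterConfig | None = None,
) -> TrioReport:
    """Produce the family candidate list: classify by inheritance, then filter.

    Requires at least one trio with an affected proband.  The candidate set
    is independent of input variant order; the report lists candidates
    grouped by proband and pattern.
    """
    cfg = cfg or FilterConfig()
    trios = [t for t in pedigree.trios if t.proband.affected == "affected"]
    if not trios:
        raise DataError("pedigree contains no trio with an affected proband")

    by_id = {v.variant_id: v for v in variants}
    ordered = sorted(by_id.values(), key=lambda r: (r.chrom, r.pos, r.alt))

    calls: list[InheritanceCall] = []
    excluded: list[ExcludedVariant] = []
    candidates: list[Candidate] = []
    # (variant_id, pattern) -> proband ids carrying it as a candidate
    candidate_probands: dict[tuple[str, str], set[str]] = {}

    for trio in trios:
        pid = trio.proband.sample_id
        patterns: dict[str, str] = {}
        for rec in ordered:
            pattern = _call_pattern(genotypes, rec.variant_id, trio, rec.is_autosomal)
            patterns[rec.variant_id] = pattern
            calls.append(InheritanceCall(rec.variant_id, pid, pattern))

        # compound hets among proband-heterozygous variants, grouped by gene
        gene_map: dict[str, list[str]] = {}
        for rec in ordered:
            ann = annotations.get(rec.variant_id)
            gene = ann.gene if ann else rec.gene
            if gene:
                gene_map.setdefault(gene, []).append(rec.variant_id)
        chet_pairs = find_compound_hets(gene_map, genotypes, trio)
        chet_partner: dict[str, str] = {}
        for v1, v2 in chet_pairs:
            chet_partner.setdefault(v1, v2)
            chet_partner.setdefault(v2, v1)

        for rec in ordered:
            vid = rec.variant_id
            ann = annotations.get(vid)
            pattern = patterns[vid]
            if pattern == "unresolved" or pattern not in PATTERNS:
                continue
            if ann is None:
                excluded.append(ExcludedVariant(vid, pattern, "missing_annotation"))
                continue
            accepted: str | None = None
            partner: str | None = None
            if pattern == "homozygous_recessive":
                dosage = genotypes.dosage(vid, pid)
                if passes_recessive_filter(ann, dosage, cfg):
                    accepted = "recessive"
                else:
                    excluded.append(
                        ExcludedVariant(
                            vid, pattern, exclusion_reason(ann, "recessive", cfg, dosage)
                        )
                    )
            else:  # de_novo / inherited_het (compound hets are a subset of hets)
                if passes_dominant_filter(ann, cfg):
                    accepted = "dominant"
                    if vid in chet_partner:
                        partner_ann = annotations.get(chet_partner[vid])
                        if partner_ann is not None and passes_dominant_filter(partner_ann, cfg):
                            pattern = "compound_het"
                            partner = chet_partner[vid]
                else:
                    excluded.append(
                        ExcludedVariant(vid, pattern, exclusion_reason(ann, "dominant", cfg))
                    )
            if accepted:
                candidates.append(
                    Candidate(
                        variant_id=vid,
                        gene=ann.gene,
                        proband_id=pid,
                        pattern=pattern,
                        segregating=False,  # resolved below
                        filter_clause=accepted,
                        partner_variant_id=partner,
                    )
                )
                candidate_probands.setdefault((vid, pattern), set()).add(pid)

    # Segregation: candidate present (same pattern) in every affected sibling
    # and not homozygous in any unaffected member.
    final: list[Candidate] = []
    for c in candidates:
        proband = pedigree[c.proband_id]
        sibs = pedigree.affected_siblings(proband)
        shared = all(
            s.sample_id in candidate_probands.get((c.variant_id, c.pattern), set())
            for s in sibs
        )
        unaffected_hom = any(
            m.affected == "unaffected" and genotypes.dosage(c.variant_id, m.sample_id) == 2
            for m in pedigree.members
            if m.sample_id in genotypes.samples
        )
        segregating = shared and len(sibs) >= 2 and not unaffected_hom
        final.append(
            Candidate(
                variant_id=c.variant_id,
                gene=c.gene,
                proband_id=c.proband_id,
                pattern=c.pattern,
                segregating=segregating,
                filter_clause=c.filter_clause,
                partner_variant_id=c.partner_variant_id,
            )
        )
    return TrioReport(candidates=final, calls=calls, excluded=excluded)
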