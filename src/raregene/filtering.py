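"""Qualifying-variant ("deleterious") filter.

A variant qualifies under the dominant model when it is loss-of-function,
or missense with reference MAF absent-or-<=0.01% and CADD phred > 20.
Under the recessive model the deleteriousness clauses are unchanged and the
per-allele frequency clause is replaced by the reference homozygous-genotype
frequency, evaluated only for homozygous carriers.

Boundary semantics are deliberate and tested: MAF exactly at the threshold
passes (<=), CADD exactly at the threshold fails (strict >).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import DataError, GenotypeMatrix, VariantRecord, _chrom_key

__all__ = [
    "CONSEQUENCE_CLASSES",
    "DEFAULT_LOF_CONSEQUENCES",
    "AnnotationRecord",
    "FilterConfig",
    "ExcludedVariant",
    "FilterResult",
    "passes_dominant_filter",
    "passes_recessive_filter",
    "exclusion_reason",
    "apply_filter",
    "consequence_class",
]

CONSEQUENCE_CLASSES = frozenset({"lof", "missense", "synonymous", "other"})

#: Raw consequence terms collapsed to the ``lof`` class by default.
DEFAULT_LOF_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_acceptor", "splice_donor", "start_lost"}
)


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant annotation: gene, consequence class, reference frequencies, CADD.

    ``maf`` / ``hom_maf`` of ``None`` mean the variant is ABSENT from the
    reference population — a different fact from an observed frequency of 0.
    """

    gene: str
    consequence: str
    maf: float | None
    hom_maf: float | None
    cadd: float

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise DataError(
                f"unknown consequence {self.consequence!r}; allowed: "
                f"{sorted(CONSEQUENCE_CLASSES)}"
            )
        for name in ("maf", "hom_maf"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise DataError(f"{name}={v} outside [0, 1]")
        if self.cadd < 0:
            raise DataError(f"cadd must be >= 0, got {self.cadd}")
        if (
            self.maf is not None
            and self.hom_maf is not None
            and self.hom_maf > self.maf
        ):
            raise DataError(
                f"hom_maf {self.hom_maf} exceeds maf {self.maf}: a homozygote carries the allele"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the qualifying-variant filter.

    Defaults reproduce the published criteria: reference MAF <= 0.01%
    (fraction 1e-4, percent-to-fraction conversion made explicit here),
    CADD phred strictly > 20, and under the recessive model a homozygous
    genotype frequency <= 1e-4.
    """

    maf_threshold: float = 1e-4
    cadd_threshold: float = 20.0
    hom_maf_threshold: float = 1e-4
    lof_consequences: frozenset[str] = DEFAULT_LOF_CONSEQUENCES

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "cadd_threshold", "hom_maf_threshold"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


def consequence_class(token: str, cfg: FilterConfig | None = None) -> str:
    """Collapse a raw consequence term to one of the four filter classes."""
    token = token.strip().lower()
    if token in CONSEQUENCE_CLASSES:
        return token
    lof = (cfg or FilterConfig()).lof_consequences
    if token in lof:
        return "lof"
    if token in {"missense_variant"}:
        return "missense"
    if token in {"synonymous_variant"}:
        return "synonymous"
    return "other"


def passes_dominant_filter(a: AnnotationRecord, cfg: FilterConfig | None = None) -> bool:
    """Dominant-model qualifying test: LoF, or rare deleterious missense."""
    cfg = cfg or FilterConfig()
    if a.consequence == "lof":
        return True
    if a.consequence != "missense":
        return False
    rare = a.maf is None or a.maf <= cfg.maf_threshold
    return rare and a.cadd > cfg.cadd_threshold


def passes_recessive_filter(
    a: AnnotationRecord, proband_dosage: int, cfg: FilterConfig | None = None
) -> bool:
    """Recessive-model qualifying test for a homozygous carrier.

    The deleteriousness clauses (LoF, or missense with CADD above threshold)
    are those of the dominant model; the rarity clause switches from the
    per-allele MAF to the reference homozygous-genotype frequency.
    """
    cfg = cfg or FilterConfig()
    if proband_dosage is None:
        raise DataError("proband dosage is MISSING; resolve genotypes before filtering")
    if proband_dosage not in (0, 1, 2):
        raise DataError(f"dosage must be in {{0,1,2}}, got {proband_dosage}")
    if proband_dosage != 2:
        return False
    deleterious = a.consequence == "lof" or (
        a.consequence == "missense" and a.cadd > cfg.cadd_threshold
    )
    rare_hom = a.hom_maf is None or a.hom_maf <= cfg.hom_maf_threshold
    return deleterious and rare_hom


#: Reason codes emitted in the excluded-variant report.
EXCLUSION_REASONS = (
    "missing_annotation",
    "not_missense_or_lof",
    "maf_above_threshold",
    "cadd_at_or_below_threshold",
    "hom_maf_above_threshold",
    "not_homozygous",
)


def exclusion_reason(
    a: AnnotationRecord, model: str, cfg: FilterConfig, dosage: int | None = None
) -> str | None:
    """First failing clause of the filter, or ``None`` when the variant passes."""
    if model == "dominant":
        if passes_dominant_filter(a, cfg):
            return None
        if a.consequence not in ("lof", "missense"):
            return "not_missense_or_lof"
        if a.maf is not None and a.maf > cfg.maf_threshold:
            return "maf_above_threshold"
        return "cadd_at_or_below_threshold"
    if model == "recessive":
        if dosage != 2:
            return "not_homozygous"
        if passes_recessive_filter(a, dosage, cfg):
            return None
        if a.consequence not in ("lof", "missense"):
            return "not_missense_or_lof"
        if a.consequence == "missense" and a.cadd <= cfg.cadd_threshold:
            return "cadd_at_or_below_threshold"
        return "hom_maf_above_threshold"
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class ExcludedVariant:
    variant_id: str
    model: str
    reason: str


@dataclass
class FilterResult:
    """Outcome of :func:`apply_filter`: qualifying (variant_id, model) pairs
    plus an audit trail of excluded variants (nothing is silently dropped)."""

    qualifying: list[tuple[str, str]]
    excluded: list[ExcludedVariant]

    @property
    def qualifying_ids(self) -> list[str]:
        return [vid for vid, _ in self.qualifying]


def apply_filter(
    variants: Sequence[VariantRecord],
    annotations: Mapping[str, AnnotationRecord],
    genotypes: GenotypeMatrix | None,
    model: str = "dominant",
    cfg: FilterConfig | None = None,
) -> FilterResult:
    """Apply the qualifying filter to a variant set.

    ``model`` is ``dominant``, ``recessive`` or ``both``.  Under the
    recessive model a variant qualifies when at least one sample is a
    homozygous carrier and the annotation clauses hold; ``genotypes`` is
    required for that model.  Output is sorted by (chrom, pos, alt) and the
    operation is idempotent.
    """
    cfg = cfg or FilterConfig()
    models = ("dominant", "recessive") if model == "both" else (model,)
    if "recessive" in models and genotypes is None:
        raise DataError("recessive model requires genotypes")

    qualifying: list[tuple[str, str]] = []
    excluded: list[ExcludedVariant] = []
    ordered = sorted(variants, key=lambda r: (_chrom_key(r.chrom), r.pos, r.alt))
    for rec in ordered:
        vid = rec.variant_id
        ann = annotations.get(vid)
        for m in models:
            if ann is None:
                excluded.append(ExcludedVariant(vid, m, "missing_annotation"))
                continue
            if m == "dominant":
                reason = exclusion_reason(ann, "dominant", cfg)
            else:
                dosages = [d for d in genotypes.sample_dosages(vid).values() if d is not None]
                hom = 2 if any(d == 2 for d in dosages) else (max(dosages) if dosages else 0)
                reason = exclusion_reason(ann, "recessive", cfg, dosage=hom)
            if reason is None:
                qualifying.append((vid, m))
            else:
                excluded.append(ExcludedVariant(vid, m, reason))
    return FilterResult(qualifying=qualifying, excluded=excluded)
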