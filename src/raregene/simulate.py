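"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a single-gene targeted-sequencing study: a panel of
candidate sites with consequence classes and annotations, a large diploid
reference population (Hardy-Weinberg genotype counts at every site), a case
cohort whose carrier odds at qualifying sites are enriched by a configurable
odds ratio (1 = null), and nuclear-family trios with a planted recessive
genotype configuration (heterozygous parents, homozygous affected children).

Ground truth (which sites qualify under the default filter, which variant
was planted) is emitted alongside every dataset so recovery and calibration
experiments can be scored programmatically.  A single integer seed fixes
everything; per-site generator sub-streams are derived deterministically
from (seed, stream, site index), so outputs are byte-identical across runs
and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import BurdenTable, build_2x2
from .filtering import AnnotationRecord, FilterConfig, passes_dominant_filter
from .io import (
    DataError,
    GenotypeMatrix,
    PedMember,
    Pedigree,
    ReferenceSite,
    ReferenceSiteTable,
    VariantRecord,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SitePanel",
    "make_site_panel",
    "simulate_reference",
    "simulate_cohort",
    "simulate_trio",
    "simulate_burden_replicate",
]

_BASES = ("A", "C", "G", "T")

# generator sub-stream ids
_STREAM_PANEL = 0
_STREAM_REFERENCE = 1
_STREAM_COHORT = 2
_STREAM_TRIO = 3


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the targeted-sequencing study the pipeline reproduces:
    417 diploid cases against a reference panel of 19,960 diploid
    individuals, with an aggregate qualifying-allele frequency of 0.25%
    (qualifying alleles per reference individual) and case enrichment on
    the odds scale (``enrichment_or`` = 1 is the null).
    """

    n_cases: int = 417
    n_reference: int = 19_960
    n_sites: int = 60
    consequence_mix: tuple[tuple[str, float], ...] = (
        ("lof", 0.05),
        ("missense", 0.45),
        ("synonymous", 0.35),
        ("other", 0.15),
    )
    baseline_qualifying_carrier_freq: float = 0.0025
    enrichment_or: float = 1.0
    #: fraction of missense sites planned to satisfy the qualifying filter
    missense_qualifying_rate: float = 0.5
    #: probability that a qualifying site is ABSENT from the reference annotation
    absent_annotation_rate: float = 0.3
    #: per-consequence CADD phred ranges (qualifying missense is drawn above
    #: the filter threshold, disqualified missense below it)
    cadd_ranges: tuple[tuple[str, tuple[float, float]], ...] = (
        ("lof", (10.0, 45.0)),
        ("missense", (0.5, 45.0)),
        ("synonymous", (0.0, 20.0)),
        ("other", (0.0, 25.0)),
    )
    gene: str = "GENE1"
    chrom: str = "3"
    start_pos: int = 49_920_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.consequence_mix)
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"consequence_mix proportions sum to {total}, expected 1")
        if not (0.0 <= self.baseline_qualifying_carrier_freq <= 1.0):
            raise DataError("baseline_qualifying_carrier_freq outside [0, 1]")
        if self.enrichment_or <= 0:
            raise DataError("enrichment_or must be positive")


@dataclass(frozen=True)
class TruthRecord:
    variant_id: str
    consequence: str
    true_freq: float
    qualifying: bool
    planted: bool = False


@dataclass
class SitePanel:
    """A simulated single-gene site panel with annotations and ground truth."""

    records: list[VariantRecord]
    annotations: dict[str, AnnotationRecord]
    truth: list[TruthRecord]
    config: SimConfig

    @property
    def qualifying_ids(self) -> list[str]:
        return [t.variant_id for t in self.truth if t.qualifying]

    def true_freq(self, variant_id: str) -> float:
        for t in self.truth:
            if t.variant_id == variant_id:
                return t.true_freq
        raise KeyError(variant_id)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.truth])


def _rng(cfg: SimConfig, stream: int, index: int, extra: int | None = None) -> np.random.Generator:
    key = [cfg.seed, stream, index] if extra is None else [cfg.seed, stream, index, extra]
    return np.random.default_rng(key)


def _draw_consequence(u: float, mix: tuple[tuple[str, float], ...]) -> str:
    acc = 0.0
    for cons, w in mix:
        acc += w
        if u < acc:
            return cons
    return mix[-1][0]


def make_site_panel(cfg: SimConfig) -> SitePanel:
    """Draw the site panel: positions, alleles, consequences, annotations, truth.

    Qualifying sites share the aggregate carrier budget equally, so each
    gets true allele frequency ``baseline / (2 K)`` for ``K`` qualifying
    sites (rare-variant regime: carrier frequency ~ 2f per site); that also
    keeps every qualifying site's reference MAF at or below the filter
    threshold.  Disqualified missense sites violate exactly one clause —
    either CADD at/below threshold, or a common allele frequency.
    """
    filter_cfg = FilterConfig()
    # pass 1: consequences and qualifying roles
    roles: list[tuple[str, bool, str]] = []  # (consequence, qualifying, violation)
    for i in range(cfg.n_sites):
        rng = _rng(cfg, _STREAM_PANEL, i)
        cons = _draw_consequence(rng.random(), cfg.consequence_mix)
        if cons == "lof":
            roles.append((cons, True, ""))
        elif cons == "missense":
            if rng.random() < cfg.missense_qualifying_rate:
                roles.append((cons, True, ""))
            else:
                roles.append((cons, False, "cadd" if rng.random() < 0.5 else "maf"))
        else:
            roles.append((cons, False, "consequence"))
    n_qual = sum(1 for _, q, _ in roles if q)
    f_qual = (
        min(cfg.baseline_qualifying_carrier_freq / (2 * n_qual), filter_cfg.maf_threshold)
        if n_qual
        else 0.0
    )

    cadd_ranges = dict(cfg.cadd_ranges)
    records: list[VariantRecord] = []
    annotations: dict[str, AnnotationRecord] = {}
    truth: list[TruthRecord] = []
    for i, (cons, qualifying, violation) in enumerate(roles):
        rng = _rng(cfg, _STREAM_PANEL, i, 1)
        pos = cfg.start_pos + 50 * (i + 1)
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(rng.integers(3) + _BASES.index(ref) + 1) % 4]
        lo, hi = cadd_ranges[cons]
        if qualifying:
            freq = f_qual
            if cons == "missense":
                cadd = float(rng.uniform(max(lo, filter_cfg.cadd_threshold + 0.5), hi))
            else:
                cadd = float(rng.uniform(lo, hi))
            absent = rng.random() < cfg.absent_annotation_rate
            maf = None if absent else freq
            hom_maf = None if absent else freq * freq
        elif violation == "cadd":
            freq = f_qual if f_qual > 0 else 1e-5
            cadd = float(rng.uniform(min(lo, 1.0), filter_cfg.cadd_threshold))
            maf, hom_maf = freq, freq * freq
        elif violation == "maf":
            freq = float(10 ** rng.uniform(-3.5, -1.5))
            cadd = float(rng.uniform(max(lo, filter_cfg.cadd_threshold + 0.5), hi))
            maf, hom_maf = freq, freq * freq
        else:  # synonymous / other
            freq = float(10 ** rng.uniform(-5.0, -1.5))
            cadd = float(rng.uniform(lo, hi))
            maf, hom_maf = freq, freq * freq
        rec = VariantRecord(
            chrom=cfg.chrom, pos=pos, ref=ref, alt=alt, gene=cfg.gene, consequence=cons
        )
        ann = AnnotationRecord(
            gene=cfg.gene, consequence=cons, maf=maf, hom_maf=hom_maf, cadd=round(cadd, 3)
        )
        # truth flag is the filter's own verdict on the emitted annotation
        assert passes_dominant_filter(ann, filter_cfg) == qualifying, (
            "generator produced an annotation inconsistent with its planned role"
        )
        records.append(rec)
        annotations[rec.variant_id] = ann
        truth.append(TruthRecord(rec.variant_id, cons, freq, qualifying))
    return SitePanel(records=records, annotations=annotations, truth=truth, config=cfg)


def _hwe_probs(f: float) -> list[float]:
    return [(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f]


def simulate_reference(
    panel: SitePanel, cfg: SimConfig | None = None, *, replicate_seed: int | None = None
) -> ReferenceSiteTable:
    """Draw the reference panel's per-site genotype counts under Hardy-Weinberg.

    Genotype counts at each site are multinomial over (hom-ref, het,
    hom-alt) for ``n_reference`` individuals, so allele and homozygote
    counts are exactly consistent (allele_count = het + 2 x hom-alt over
    allele_number = 2 x n_reference).
    """
    cfg = cfg or panel.config
    base = cfg if replicate_seed is None else replace(cfg, seed=replicate_seed)
    table = ReferenceSiteTable()
    for i, t in enumerate(panel.truth):
        rng = _rng(base, _STREAM_REFERENCE, i)
        n_homref, n_het, n_homalt = rng.multinomial(cfg.n_reference, _hwe_probs(t.true_freq))
        table[t.variant_id] = ReferenceSite(
            allele_count=int(n_het + 2 * n_homalt),
            allele_number=2 * cfg.n_reference,
            homozygote_count=int(n_homalt),
        )
    return table


def _case_carrier_prob(f: float, enrichment_or: float) -> float:
    q = 2.0 * f * (1.0 - f) + f * f  # control carrier frequency
    odds = enrichment_or * q / (1.0 - q)
    return odds / (1.0 + odds)


def simulate_cohort(
    panel: SitePanel, cfg: SimConfig | None = None, *, replicate_seed: int | None = None
) -> tuple[list[VariantRecord], GenotypeMatrix, dict[str, AnnotationRecord]]:
    """Draw the case cohort's genotypes.

    At qualifying sites each case is a (heterozygous) carrier with
    probability set so that case carrier odds equal control odds times
    ``enrichment_or`` — the rare-variant regime of the study, where every
    observed case variant is a single heterozygous carrier.  Non-qualifying
    sites are drawn from Hardy-Weinberg at the control frequency.
    """
    cfg = cfg or panel.config
    base = cfg if replicate_seed is None else replace(cfg, seed=replicate_seed)
    sample_ids = [f"CASE_{j + 1:04d}" for j in range(cfg.n_cases)]
    rows = []
    for i, t in enumerate(panel.truth):
        rng = _rng(base, _STREAM_COHORT, i)
        if t.qualifying:
            p = _case_carrier_prob(t.true_freq, cfg.enrichment_or)
            dosages = (rng.random(cfg.n_cases) < p).astype(np.int8)
        else:
            dosages = rng.binomial(2, t.true_freq, cfg.n_cases).astype(np.int8)
        rows.append(dosages)
    df = pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, cfg.n_cases), dtype=np.int8),
        index=[t.variant_id for t in panel.truth],
        columns=sample_ids,
    )
    return list(panel.records), GenotypeMatrix(df), dict(panel.annotations)


def simulate_burden_replicate(
    panel: SitePanel, replicate_seed: int, cfg: SimConfig | None = None
) -> BurdenTable:
    """Counts-level replicate of the case/reference burden comparison.

    Draws only the aggregate qualifying-allele counts (site-level binomial
    and multinomial draws, no per-individual genotype matrix), in strict
    allele units on both arms — the fast path for null-calibration and
    power experiments.
    """
    cfg = cfg or panel.config
    base = replace(cfg, seed=replicate_seed)
    case_q = 0
    ctrl_q = 0
    for i, t in enumerate(panel.truth):
        if not t.qualifying:
            continue
        rng_ref = _rng(base, _STREAM_REFERENCE, i)
        _, n_het, n_homalt = rng_ref.multinomial(cfg.n_reference, _hwe_probs(t.true_freq))
        ctrl_q += int(n_het + 2 * n_homalt)
        rng_case = _rng(base, _STREAM_COHORT, i)
        p = _case_carrier_prob(t.true_freq, cfg.enrichment_or)
        case_q += int(rng_case.binomial(cfg.n_cases, p))
    return build_2x2(case_q, 2 * cfg.n_cases, ctrl_q, 2 * cfg.n_reference, unit="allele")


def default_planted_site(panel: SitePanel) -> str:
    """First qualifying missense site — a natural recessive candidate."""
    for t in panel.truth:
        if t.qualifying and t.consequence == "missense":
            return t.variant_id
    raise DataError("panel contains no qualifying missense site to plant")


def simulate_trio(
    panel: SitePanel,
    cfg: SimConfig | None = None,
    planted: str | None = None,
    *,
    n_affected: int = 2,
    replicate_seed: int | None = None,
) -> tuple[list[VariantRecord], GenotypeMatrix, Pedigree, list[TruthRecord]]:
    """Draw a nuclear family with a planted recessive configuration.

    Both parents are heterozygous at the planted site and every affected
    child homozygous (the discovery configuration for a recessive candidate
    shared by affected siblings).  At decoy sites parental genotypes are
    drawn from Hardy-Weinberg at the true frequency and children receive
    one Mendelian-transmitted allele from each parent.
    """
    cfg = cfg or panel.config
    base = cfg if replicate_seed is None else replace(cfg, seed=replicate_seed)
    planted = planted or default_planted_site(panel)
    if planted not in {t.variant_id for t in panel.truth}:
        raise DataError(f"planted variant {planted!r} is not in the panel")

    children = [f"PROBAND_{k + 1}" for k in range(n_affected)]
    samples = ["FATHER", "MOTHER"] + children
    rows = []
    for i, t in enumerate(panel.truth):
        rng = _rng(base, _STREAM_TRIO, i)
        if t.variant_id == planted:
            rows.append([1, 1] + [2] * n_affected)
            continue
        father, mother = rng.binomial(2, t.true_freq, 2)
        kid_dosages = []
        for _ in children:
            pat = int(rng.random() < father / 2.0)
            mat = int(rng.random() < mother / 2.0)
            kid_dosages.append(pat + mat)
        rows.append([int(father), int(mother)] + kid_dosages)
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int8),
        index=[t.variant_id for t in panel.truth],
        columns=samples,
    )
    members = [
        PedMember("FATHER", None, None, "male", "unaffected", family_id="FAM1"),
        PedMember("MOTHER", None, None, "female", "unaffected", family_id="FAM1"),
    ] + [
        PedMember(kid, "FATHER", "MOTHER", "unknown", "affected", family_id="FAM1")
        for kid in children
    ]
    truth = [replace(t, planted=(t.variant_id == planted)) for t in panel.truth]
    return list(panel.records), GenotypeMatrix(df), Pedigree(members), truth
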