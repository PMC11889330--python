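# Methods

## Scope and model

`raregene` implements a candidate-gene rare-variant workflow: trio-based
inheritance classification, a deterministic qualifying-variant filter,
ACMG/AMP evidence combination, and a collapsing (burden) association test
of a single gene's qualifying alleles against a reference population. There
is no fitted statistical model; every analysis step is a deterministic rule
or an exact test, which is why reproducibility is exact given identical
inputs and configuration.

## Qualifying-variant filter

A variant qualifies under the **dominant model** iff

* consequence is loss-of-function (stop-gain, frameshift, canonical splice,
  start-loss — collapsed to the `lof` class by the annotation table), or
* consequence is missense **and** reference MAF is absent or ≤ `maf_threshold`
  **and** CADD phred > `cadd_threshold`.

Defaults: `maf_threshold = 1e-4` (0.01% expressed as a fraction — the
percent-to-fraction conversion is made explicit here), `cadd_threshold = 20`
(strict inequality), `hom_maf_threshold = 1e-4`. Boundary semantics are
deliberate: MAF exactly 1e-4 passes (≤), CADD exactly 20 fails (>). Under
the **recessive model** the deleteriousness clauses are unchanged and only
the rarity clause switches: the reference *homozygous-genotype* frequency
must be absent or ≤ `hom_maf_threshold`, and the test applies only to
homozygous carriers. This is how a variant with a common allele frequency
(e.g. 0.005) but a single reference homozygote (frequency 1e-4) is retained
as a recessive candidate while failing the dominant filter.

`ABSENT` (not observed in the reference) is represented as `None` and is
distinct from an observed frequency of 0; both satisfy the rarity clause
but they are different facts, and the distinction is preserved through the
annotation table round trip.

Variants lacking annotation are never silently dropped: they appear in the
excluded report with reason `missing_annotation`, alongside the per-clause
reason codes (`not_missense_or_lof`, `maf_above_threshold`,
`cadd_at_or_below_threshold`, `hom_maf_above_threshold`, `not_homozygous`).
One published targeted-sequencing variant (a missense with CADD 6.248)
fails the stated criteria although the source study listed it among its
nine variants; the pipeline applies the stated rule and emits the variant
in the excluded report rather than special-casing it.

## Trio classification

Dosage triples (proband, father, mother) over {0, 1, 2, MISSING} at
autosomal sites map to: `(2, ≥1, ≥1) → homozygous_recessive` (canonical
configuration (2,1,1): heterozygous unaffected parents), `(≥1, 0, 0) →
de_novo`, `(1, ≥1 carrier parent) → inherited_het`, and everything else —
any MISSING dosage, a non-carrier proband, or a Mendelian-inconsistent
combination such as (2,1,0) — `unresolved`. We deliberately accept a
homozygous-by-descent call when a parent is itself homozygous (2,2,1): the
transmission is Mendelian-consistent and the recessive interpretation is
unchanged; only (2,1,1) arises in practice at rare-variant frequencies.
Non-autosomal sites are labelled `unresolved`; hemizygosity rules are out
of scope.

Compound heterozygotes are called only from unambiguous parental origin:
both variants proband-heterozygous in the same gene, one carried by the
father only and the other by the mother only. Pairs where either variant
could have come from either parent are not called — conservative and
deterministic, with no statistical phasing.

The pipeline order is classify-then-filter. The candidate set is invariant
to input variant order (tested). A candidate is flagged **segregating**
when every affected sibling (same two parents) carries it as a candidate
with the same pattern, there are at least two affected siblings, and no
unaffected member is a homozygous carrier; heterozygous unaffected parents
are consistent with recessive segregation. The flag is surfaced to the ACMG
layer as a *suggested* PP1 — never auto-applied, because evidence
assignment is the analyst's decision.

## ACMG/AMP combination

The engine implements the published 2015 combining rules in full over tier
counts (very strong / strong / moderate / supporting on the pathogenic
side; stand-alone / strong / supporting on the benign side). Rules are
evaluated as ≥-thresholds, so adding evidence never weakens a class except
through the explicit conflict rule: when any pathogenic-side rule and any
benign-side rule hold simultaneously the classification is VUS. BA1 is
stand-alone benign but still subject to the conflict rule. An exhaustive
truth-table test checks the engine against an independently transcribed
rule table over all tier-count combinations in a bounded universe
(12,000 combinations).

The engine classifies from supplied codes only; deriving codes from data
(ClinVar lookups, domain intersections, population statistics) is out of
scope.

## Burden test

Case qualifying count = sum of qualifying-variant allele dosages over case
samples; each variant contributes its allele count rather than one count
per carrier (identical in the rare-variant regime where every carrier is
heterozygous at one site). The case denominator is always alleles
(2 × individuals). Two control-denominator conventions are provided:

* `as_published` (default) — qualifying allele count over the *number of
  individuals* in the reference panel, replicating the published table's
  mixed units (e.g. 50 / 19,960 = 0.25%);
* `allele` — alleles on both arms, the strictly consistent 2×2.

The two-tailed Fisher exact p sums hypergeometric point probabilities
≤ P(observed)·(1 + 1e-7) over all tables with the observed margins,
computed in log space via `lgamma` with a max-shifted exponential sum, and
clipped to [0, 1]. The 1e-7 relative tolerance for ties is the convention
of mainstream statistical software. The p-value depends only on the table,
not on the units convention chosen for the odds ratio.

The odds-ratio point estimate is the sample cross-product ad/bc; with any
zero cell the Haldane–Anscombe correction (+0.5 per cell) is applied, with
a logged notice when it was not requested explicitly. The confidence
interval is Woolf's normal approximation on log OR. The source study prints
an OR (5.492) and CI inconsistent with its own table cells (ad/bc = 4.344);
since the estimator used there is unstated, this package reports the sample
estimator and does not attempt to reproduce the printed OR. The p-value is
reproduced exactly.

## Synthetic cohorts

The generator emulates a single-gene targeted-sequencing study. Defaults
are the study's own conditions: 417 diploid cases, a reference panel of
19,960 diploid individuals, an aggregate qualifying-allele frequency of
0.25% (qualifying alleles per reference individual), and a case enrichment
odds ratio (1 = null). A 60-site panel with consequence mix 5% LoF / 45%
missense / 35% synonymous / 15% other and half of missense sites planned
as qualifying yields ≈ 16–20 qualifying sites, so each qualifying site's
true allele frequency (baseline / 2K) stays at or below the 1e-4 MAF
threshold — the generator's qualifying flags are, by construction and by a
cross-module test, exactly the filter's verdicts on the emitted annotation
table.

Reference genotype counts are multinomial over Hardy–Weinberg class
probabilities, so allele and homozygote counts are exactly consistent; HWE
is the minimal population model consistent with a homozygote-frequency
column. Case carrier probability at qualifying sites satisfies
odds(case) = OR × odds(control); carriers are heterozygous (rare-variant
regime). Trios plant the recessive configuration (parents heterozygous,
affected children homozygous) and transmit decoy alleles Mendelianly from
Hardy–Weinberg parents. No linkage disequilibrium, relatedness, population
structure or sequencing-error model is simulated — passing recovery and
calibration tests therefore demonstrate correctness of the discovery logic
under idealized genotypes, not robustness to genotyping error or
stratification in real data.

Randomness: one integer seed; per-site sub-streams are derived from
(seed, stream-id, site-index) so outputs are byte-identical across runs and
independent of generation order.

## Experiment sizes and numerical choices

* Null calibration: 2000 counts-level replicates at the full arm sizes
  (site-level multinomial/binomial draws; no per-individual genotype
  emission), strict allele units on both arms (a mixed-unit table is not a
  calibrated 2×2 under the null). The α = 0.05 rejection rate is required
  to stay within 0.05 + 3·binomial SE; the exact test is conservative on
  discrete tables, and observed rates are ≈ 0.02–0.03.
* Trio recovery: 100 generator seeds, full genotype-level simulation
  (60 sites, 4 samples); the planted variant is always recovered, and on
  seeds where recorded truth says no decoy forms a filter-passing
  configuration, precision = recall = 1.
* Fisher oracle sweep: exhaustive over all 2×2 tables with every margin
  ≤ 30 (> 100,000 tables) against a brute-force integer-combinatorics
  enumerator, to 1e-9 relative tolerance; spot checks against
  `scipy.stats.fisher_exact` on random tables.
* Reference-table validation tolerates 5% relative / 5e-5 absolute
  disagreement between a stated MAF column and the count-derived value
  (published tables round aggressively); larger disagreement is an error.

## Known limitations

* Autosomal diploid genotypes only; X/Y sites are read but classified
  `unresolved`.
* No covariate adjustment (logistic/Firth), no dispersion-robust collapsing
  tests (SKAT family), no genome-wide multiplicity control — single-gene
  analysis by design.
* Consequence classes, CADD scores and reference frequencies are inputs;
  the package performs no annotation itself.
* Compound-het calling requires unambiguous parental origin and will miss
  true trans pairs whose origin is ambiguous from single-site genotypes.
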