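# Methods

This note documents the models behind `snparray`: what the synthetic
data generator emulates, how each filtering and selection rule is
defined at its boundaries, the numerical conventions, and the design
choices made where the workflow it reimplements left the design open.

## Coordinate and genotype conventions

All genomic coordinates are 1-based with inclusive intervals (the
VCF/GFF convention), everywhere. Biallelic genotypes are coded `aa`
(homozygous reference), `ab`, `bb`, and `--` (missing/no-call); an
adapter to VCF GT notation lives in the I/O layer. Percentages are
printed to one decimal using round-half-even, and every reported
percentage in the package goes through the same `round1` helper.

## The synthetic study

The generator fabricates the full input set of an array-design study.
All randomness flows from an explicit integer seed (numpy PCG64);
identical seeds give byte-identical outputs. Defaults
(`StudyConfig`) describe a desk-scale study:

| Parameter | Default | Meaning |
| --- | --- | --- |
| genome | 3 × 300 kb chromosomes + 20 contigs of 2–20 kb | coordinate frame with unplaced sequence |
| SNP density | 3 /kb | true variants, unique positions, ref = genome base |
| AF spectrum | Beta(0.8, 0.8) per group | U-shaped folded spectrum; per-group AFs share a common draw with probability 0.5 (`af_correlation`) |
| platforms | highcov 0.80 detection / 0.25 FP·kb⁻¹, gbs 0.30 / 0.10, rad 0.25 / 0.10, rnaseq 0.15 / 0.05 | detection probability per true SNP and platform-private false positives |
| AF estimates | binomial resample of the truth at 2 × (8–50) allele copies | platform-specific estimation resolution |
| families | 3 families × 50 progeny; 0.2 % genotyping error, 2 % missingness, 5 % distorted markers at tilt strength 1.5 | inputs to the family filters |
| populations | 2 panels × 24 samples, Hardy–Weinberg, 2 % missing | inputs to the MAF filter |
| array test | 40 samples/group, per-sample target call rate U(0.99, 1.0), 1 % marker failure | post-design genotyping run |

Where the original workflow's data did not state a magnitude (error
and missingness rates, platform detection power), the defaults are
free parameters chosen once as plausible values for these assay types,
not estimates of any particular dataset.

The GBS pipeline is run twice per study — emulating two read-trim
settings of the same tag data — and deduplicated by identical
flank+allele sequence, the earliest source winning. Candidate ids are
derived from placement and alternate allele, so re-detections of one
variant across runs share an id.

**Segregation distortion** is modeled as exponential tilting of the
Mendelian class probabilities: class weight ∝ p·exp(s·#b-alleles).
One knob (`s`), nesting the Mendelian null at s = 0. **Mendelian
errors** replace a cell with a different uniformly chosen genotype; the
returned truth labels record every injected cell, and a cell is
*detectable* only if the replacement is inconsistent with the parents
(e.g. any replacement under *ab* × *ab* is undetectable by
transmission logic — passing tests therefore quantify sensitivity on
detectable cells only). **sdY** is modeled as presence/absence — males
yield calls at sdY markers, females no-calls — matching the
male-limited biology of the salmonid sex gene and the concordance
check performed downstream; allelic variation at sdY is not modeled.

What the simulator deliberately does **not** emulate: read-level data
(no FASTQ, no sequencing-error model), linkage disequilibrium between
markers, population structure within groups, assay chemistry (cluster
intensities, off-target variants). Consequently, passing tests
demonstrate the correctness of the filtering/selection/reporting
machinery under idealized statistical structure, not the biological
performance of any real array.

## Filters

Every printed inequality is applied exactly as stated, each with a
dedicated boundary unit test: family missingness fails strictly above
0.5; the discovery-stage MAF floor is inclusive (≥ 0.05) while the GBS
priority criterion (b) is strict (> 0.05) — the two thresholds are
printed differently in the source workflow and are kept distinct (both
configurable); record-QC bounds are inclusive on both ends; sample QC
requires call rate strictly above 0.97, and the run-level mean of
passing samples strictly above 0.98.

A marker carried by several families is removed only when it fails in
*all* families where it is testable. Records with missing required
fields receive a distinct `not_testable` status and are never silently
passed. The segregation chi-square skips uninformative crosses
(*aa* × *aa*, *bb* × *bb*, *aa* × *bb*) and excludes genotypes
impossible under the cross from the table (those are the Mendelian
filter's concern). No multiple-testing correction is applied by
default — an optional Bonferroni flag exists — and the test is
per-family; whether the original analysis pooled families is unknown,
so both interpretations remain available via `combine_family_reports`.

A note on power: with progeny counts drawn multinomially at class
probabilities (0.4, 0.4, 0.2) and n = 100, the chi-square test's power
at α = 0.01 is ≈ 0.66 (noncentral χ², 2 df, λ = 12) — the often-cited
"40:40:20 gives χ² = 12" example describes the *observed* table, which
does reject. The test suite checks the worked example exactly and
verifies power > 0.9 at n = 250 (λ = 30), where it genuinely holds.

**Alignment uniqueness** is exact substring counting of the
flank+allele sequence and its reverse complement over all genome
sequences, overlapping matches included; the pass criterion is exactly
one placement. This is deterministic and mapper-free; mismatches and
indels are out of scope at toy-genome scale. A palindromic query
(equal to its own reverse complement) counts each physical site twice
— once per strand — and so can never pass the single-placement
criterion; this conservative behaviour is intentional.

## Panel assembly

AF strata are rare = [0.05, 0.15) and common = [0.15, 0.85], exactly;
an absent AF excludes a candidate from the strata. The rare pool spans
intergenic and intragenic SNPs while the common pool is restricted to
SNPs outside transcripts, encoded as pool predicates.

The spacing rule had to be chosen (the source workflow states only
"~900 kb" / "~62 kb" targets): the default is fixed-window
one-per-window greedy — partition each sequence into consecutive
target-sized windows anchored at bp 1, keep the best candidate per
nonempty window — because it is deterministic and testable, and it
bounds consecutive picks to < 2× the target whenever intervening
windows are nonempty. A strict-greedy alternative (next pick ≥ target
beyond the last) is available via `spacing_mode="greedy"`. The ranker
is fully deterministic: external conversion score (descending), then
|AF − 0.5| (ascending), then position, then id.

Fill order is tier 1 entirely, tier 2 (sdY, unconditional, bypassing
AF/spacing/score screens) entirely, tier 3 rare then common spacing
picks, tier 4 filler by rank until the budget is exactly reached or
pools are exhausted. External conversion scores — standing in for a
vendor's proprietary in-silico conversion assessment, which is never
re-derived — are an optional per-candidate (score, label) map;
candidates labeled `not_recommended` are dropped before filling and a
top-up pass draws further common intergenic candidates, emulating a
resubmission round. The assembly audit preserves
|input| = |selected| + |dropped-with-reason| on every run.

Probes are `FLANK[REF/ALT]FLANK` with forward-strand flanks and the
variant at 1-based offset 36 of a 71-mer (offset 51 of a 101-mer for
the long transcript-comparison form); insufficient flank raises an
error naming the deficient side, and the plain-sequence form
reproduces the genome substring exactly (tested as a round-trip).

## Evaluation

The marker classifier is a surrogate for a commercial genotyping
suite's categories, using only observed call rate and genotype
classes: call-rate failure below 0.97 non-missing; else monomorphic if
one allele observed; no-minor-homozygote if heterozygotes but no
minor-allele homozygote; polymorphic-high-resolution when both
homozygote classes are observed. "Recommended" is derived as
not-a-call-rate-failure; "polymorphic" covers the first two polymorphic
categories. Proprietary cluster-resolution metrics are not modeled, so
classification here is necessarily more permissive than a real Axiom
workflow. Dish-QC is accepted as a pre-supplied per-sample boolean when
available and skipped otherwise.

Coverage windows are anchored at bp 1 per chromosome with the
truncated final window counting as a window; per-chromosome density
uses average gap = length/count and markers/Mb = count/(length/10⁶).
`coverage_report` accepts either a full assembly or a plain
(lengths, chromosome-flag) mapping pair, since only sequence lengths
enter the arithmetic — this is what allows chromosome-scale worked
examples without fabricating hundreds of Mb of sequence.

Sex prediction calls a sample male when ≥ `min_called` (default 1)
sdY markers yield genotypes; concordance is the fraction of known-sex
samples matching. With the simulator's zero sdY failure rate,
concordance is exactly 1; it degrades as sdY no-calls are introduced.

## Problem sizes in the test and acceptance runs

The test suite exercises the full pipeline at a reduced scale chosen
for quick iteration (1–2 chromosomes of 60–120 kb, budgets of
200–600 markers, 10–24 test samples); statistical calibration tests
use 2,000 null markers × 100 progeny for the segregation test, 5,000
progeny cells for Mendelian detection, and 1,000 random queries
against a 100 kb genome for placement counting. The acceptance script
runs the default study scale (~1 Mb genome, 2,000-marker budget) plus
the published-count worked examples at their stated sizes (e.g. 2,275
markers on a 58,017 kb chromosome; 15,216 contigs; 42,439 genes; 463
sexed samples).

## Known limitations

* Exact-match placement counting cannot model paralog families that
  differ by a few bases; real array design uses alignment.
* The AF spectrum and cross-group correlation are stylized; no
  site-frequency-spectrum realism or demography is attempted.
* Marker classification omits intensity-space failure modes (off-target
  variants, cluster compression), so synthetic conversion rates run
  higher than manufactured-array conversion rates.
* The simulator draws each marker independently: no LD, so spacing
  selection cannot be evaluated for tagging efficiency, only for its
  geometric guarantees.
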