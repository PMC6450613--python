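# snparray

Design and evaluation of high-density SNP genotyping arrays, modeled on
the workflow used to build salmonid Axiom arrays: candidate SNPs from
several discovery platforms (deep whole-genome sequencing of a few
individuals, genotyping-by-sequencing, RAD-seq, RNA-seq) are quality
filtered, cross-validated against each other, stratified by allele
frequency, thinned to genome-spacing targets, and assembled into a
tiered array manifest with submission-ready probes. After genotyping,
markers are classified into Axiom-style categories and the array's
performance is summarized: per-group polymorphism, cross-group sharing,
genome coverage, and genotypic sexing through male-limited *sdY*
markers.

The package is aimed at people building or evaluating genotyping arrays
for non-model species — aquaculture geneticists, molecular ecologists —
and at anyone who wants a fully seeded synthetic testbed for such a
pipeline. Every input the pipeline consumes (genome, annotation, truth
variants, platform call sets, family and population genotypes, and the
post-design genotyping runs) can be generated by the built-in simulator
with controllable statistical structure.

## The rules at the core

* **Family QC** — a marker is removed when, in *every* family carrying
  it, it shows >50 % missing progeny genotypes, a Mendelian-transmission
  error (a progeny genotype not composable from one allele of each
  parent, e.g. *bb* under *aa* × *ab*), or significant segregation
  distortion. Distortion is a chi-square goodness-of-fit against the
  Mendelian expectation — 1:1 over {*aa*, *ab*} for *aa* × *ab*
  backcross-type markers, 1:2:1 for *ab* × *ab* — with default α = 0.01.
* **Population QC** — minor allele frequency ≥ 0.05, counted over
  non-missing allele copies.
* **Record QC** (deep-sequencing calls) — an initial calling stage
  (QUAL ≥ 20, MQ ≥ 30, GQ ≥ 20, 1 ≤ DP ≤ 100) and a stricter design
  stage (5 ≤ DP ≤ 45, QUAL ≥ 20, GQ ≥ 20, MQ ≥ 30), all boundaries
  inclusive.
* **Cross-validation** — two call sets confirm one another when they
  place a variant at the same position with the same unordered allele
  pair. GBS candidates also qualify for the high-priority tier when
  detected in two populations, when MAF > 0.05 in a population, or when
  segregating in two or more families.
* **Panel assembly** — tier 1: the cross-validated high-priority set;
  tier 2: *sdY* sex markers (unconditional); tier 3: deep-sequencing
  SNPs split into rare [0.05, 0.15) and common [0.15, 0.85] AF strata
  and thinned one-per-window to ~900 kb (rare) and ~62 kb (common
  intergenic) spacing; tier 4: low-priority putative filler to the
  budget. A/T and C/G (strand-ambiguous) variants are screened out,
  flanks must be ≥ 35 bp, and probes are emitted as 71-mers with the
  variant at base 36 in `FLANK[REF/ALT]FLANK` notation.
* **Evaluation** — samples must exceed a 0.97 call rate (run flagged
  unless passing samples average > 0.98); markers are classified as
  polymorphic-high-resolution, no-minor-homozygote, monomorphic, or
  call-rate failures; sharing reports use exact Venn set algebra;
  coverage reports give markers/Mb, average gap, empty 1-Mb windows,
  contig and gene representation; a sample is sexed male when at least
  one *sdY* marker yields a call.

## Worked example

```python
from snparray import StudyConfig, run_pipeline

results = run_pipeline(StudyConfig(), seed=42)
manifest = results["manifest"]
print(len(manifest))                                               # 2000
print(results["summaries"]["nauyuk"]["pct_polymorphic_of_recommended"])  # 86.8
print(results["sex_concordance_pct"]["iceland"])                   # 100.0
```

This simulates a ~1 Mb genome (3 chromosomes plus 20 unplaced contigs,
~3 true SNPs/kb shared across four groups), four platform call sets,
three 50-progeny families and two population panels; runs every filter;
designs a 2,000-marker array; genotypes 40 test samples per group; and
evaluates it. The three printed numbers say: the manifest filled its
2,000-marker budget exactly; 86.8 % of the markers recommended in the
`nauyuk` group's run were polymorphic there; and *sdY*-based genotypic
sexing matched the simulated phenotypic sex for every Icelandic-group
sample. The same run from a shell, writing all artifacts (manifest
TSV/VCF, filter reports, coverage and sharing tables, audit log):

```bash
snparray run --seed 42 --out demo_out/
```

## Layout

| Module | Role |
| --- | --- |
| `snparray.simulate` | seeded generators for every pipeline input |
| `snparray.qc` | family/population/record QC filters |
| `snparray.crossval` | cross-platform validation, GBS priority, tier 1 |
| `snparray.panel` | AF strata, spacing selection, probes, panel assembly |
| `snparray.evaluate` | marker classification, sharing, coverage, sexing |
| `snparray.io` | FASTA / GFF3 / VCF / TSV readers and writers |
| `snparray.pipeline` | end-to-end composition (`run_pipeline`) |
| `snparray.cli` | `snparray` command-line interface |

See `docs/methods.md` for the modeling assumptions, parameter
defaults, and known limitations.
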