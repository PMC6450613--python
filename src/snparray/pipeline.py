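"""End-to-end composition: synthetic study generation, the design
pipeline (QC -> cross-validation -> panel assembly), and post-design
evaluation on simulated genotyping runs.

``simulate_study`` fabricates every input the pipeline needs with a
controllable, seeded statistical structure; ``design_panel`` runs the
full candidate-to-manifest path with per-stage audit counts;
``evaluate_panel`` simulates the genotyping of the designed array across
groups and computes the performance reports. ``run_pipeline`` is the
file-based composition used by the CLI.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import evaluate, io, qc
from .crossval import (
    build_high_priority_tier,
    cross_validate,
    gbs_priority_select,
    segregating_markers,
)
from .model import (
    CandidateSNP,
    FamilyGenotypes,
    GeneAnnotation,
    GenomeAssembly,
    PanelManifest,
    PopulationGenotypes,
    SelectionConfig,
    TrueVariant,
)
from .panel import RARE, COMMON, assemble_panel, classify_af, label_in_transcript
from .simulate import (
    FamilyTruth,
    draw_parents_hwe,
    generate_annotation,
    generate_genome,
    generate_true_variants,
    simulate_array_run,
    simulate_family,
    simulate_platform_callset,
    simulate_population,
)
from .model import PlatformProfile

GROUPS = ("fraser", "nauyuk", "treeriver", "iceland")


@dataclass
class StudyConfig:
    """Scale and noise parameters of the synthetic study.

    Defaults give a desk-scale study: a ~1 Mb genome in 3 chromosomes
    plus 20 unplaced contigs, ~3 true SNPs/kb, four discovery platforms
    with distinct detection power and false-positive load, three
    families of 50 progeny, and population panels of 24 samples.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 300_000
    n_contigs: int = 20
    contig_length_range: tuple[int, int] = (2_000, 20_000)
    snp_density_per_kb: float = 3.0
    af_distribution: tuple = ("beta", 0.8, 0.8)
    af_correlation: float = 0.5
    genes_per_mb: float = 40.0
    groups: Sequence[str] = GROUPS
    n_families: int = 3
    n_progeny: int = 50
    mendelian_error_rate: float = 0.002
    family_missing_rate: float = 0.02
    distorted_fraction: float = 0.05
    distortion_strength: float = 1.5
    n_population_samples: int = 24
    n_sdy_markers: int = 6
    budget: int = 2_000
    rare_spacing: int = 40_000
    common_spacing: int = 8_000
    n_test_samples: int = 40
    marker_failure_rate: float = 0.01
    sample_call_rate_distribution: tuple = ("uniform", 0.99, 1.0)


def default_platform_profiles() -> dict[str, PlatformProfile]:
    """The four discovery sources: deep whole-genome sequencing of few
    individuals, two reduced-representation methods, and RNA-seq."""
    return {
        "highcov": PlatformProfile(
            name="highcov", detection_prob=0.8, fp_rate_per_kb=0.25, flank_length=50,
            quality_distributions={
                "DP": ("normal", 25, 10),
                "QUAL": ("normal", 60, 25),
                "GQ": ("normal", 60, 20),
                "MQ": ("normal", 50, 12),
            },
            af_sample_size=8, af_group="nauyuk",
        ),
        "gbs": PlatformProfile(
            name="gbs", detection_prob=0.30, fp_rate_per_kb=0.10, flank_length=40,
            af_sample_size=50, af_group="fraser",
        ),
        "rad": PlatformProfile(
            name="rad", detection_prob=0.25, fp_rate_per_kb=0.10, flank_length=40,
            af_sample_size=40, af_group="nauyuk",
        ),
        "rnaseq": PlatformProfile(
            name="rnaseq", detection_prob=0.15, fp_rate_per_kb=0.05, flank_length=50,
            af_sample_size=18, af_group="fraser",
        ),
    }


@dataclass
class StudyData:
    """Everything the design pipeline consumes, plus simulation truth."""

    genome: GenomeAssembly
    annotation: GeneAnnotation
    truth: list[TrueVariant]
    truth_by_pos: dict[tuple[str, int], TrueVariant]
    callsets: dict[str, list[CandidateSNP]]
    gbs_runs: list[list[CandidateSNP]]
    families: list[FamilyGenotypes]
    family_truths: list[FamilyTruth]
    populations: dict[str, PopulationGenotypes]
    sdy_candidates: list[CandidateSNP]
    config: StudyConfig


def _marker_id(v: CandidateSNP | TrueVariant) -> str:
    return f"{v.seq_name}:{v.pos}"


def simulate_study(config: StudyConfig = StudyConfig(), seed: int = 0) -> StudyData:
    """Generate the full synthetic study. All randomness derives from
    ``seed`` through fixed offsets, so a seed fixes the whole study."""
    genome = generate_genome(
        config.n_chromosomes,
        config.chromosome_length,
        config.n_contigs,
        config.contig_length_range,
        seed=seed,
    )
    annotation = generate_annotation(genome, config.genes_per_mb, seed=seed + 1)
    truth = generate_true_variants(
        genome,
        config.snp_density_per_kb,
        config.af_distribution,
        groups=config.groups,
        af_correlation=config.af_correlation,
        seed=seed + 2,
    )
    truth_by_pos = {v.key: v for v in truth}
    profiles = default_platform_profiles()
    callsets = {}
    for k, (name, profile) in enumerate(profiles.items()):
        callsets[name] = simulate_platform_callset(
            truth, genome, profile, seed=seed + 10 + k
        )
    # the GBS pipeline is run twice (different read-trim settings); the
    # two runs see the same truth with independent detection noise and
    # are deduplicated downstream
    gbs_profile = profiles["gbs"]
    gbs_runs = [
        callsets["gbs"],
        simulate_platform_callset(truth, genome, gbs_profile, seed=seed + 20),
    ]
    dedup, _ = qc.deduplicate_candidates(gbs_runs)
    callsets["gbs"] = dedup

    gbs_truth = [v for v in truth if v.key in
                 {(c.seq_name, c.pos) for c in callsets["gbs"]}]
    families = []
    family_truths = []
    for i in range(config.n_families):
        group = "fraser" if i % 2 == 0 else "iceland"
        marker_ids = [_marker_id(v) for v in gbs_truth]
        cross = draw_parents_hwe(gbs_truth, group, marker_ids, seed=seed + 30 + i)
        fam, fam_truth = simulate_family(
            cross,
            config.n_progeny,
            family_id=f"fam{i + 1}",
            mendelian_error_rate=config.mendelian_error_rate,
            missing_rate=config.family_missing_rate,
            distorted_fraction=config.distorted_fraction,
            distortion_strength=config.distortion_strength,
            seed=seed + 40 + i,
        )
        families.append(fam)
        family_truths.append(fam_truth)
    populations = {
        group: simulate_population(
            gbs_truth,
            group,
            config.n_population_samples,
            missing_rate=0.02,
            marker_ids=[_marker_id(v) for v in gbs_truth],
            seed=seed + 50 + j,
        )
        for j, group in enumerate(("nauyuk", "iceland"))
    }
    # sdY markers: male-limited sex-gene variants, placed on chromosome 1
    rng = np.random.default_rng(seed + 60)
    chrom = genome.chromosomes[0]
    taken = {v.pos for v in truth if v.seq_name == chrom}
    sdy: list[CandidateSNP] = []
    while len(sdy) < config.n_sdy_markers:
        pos = int(rng.integers(100, len(genome.sequences[chrom]) - 100))
        if pos in taken:
            continue
        taken.add(pos)
        ref = genome.base(chrom, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sdy.append(
            CandidateSNP(
                id=f"sdy_{len(sdy) + 1:02d}", platform="sdy", seq_name=chrom,
                pos=pos, ref=ref, alt=alt,
                left_flank=genome.subseq(chrom, pos - 50, pos - 1),
                right_flank=genome.subseq(chrom, pos + 1, pos + 50),
            )
        )
    return StudyData(
        genome=genome,
        annotation=annotation,
        truth=truth,
        truth_by_pos=truth_by_pos,
        callsets=callsets,
        gbs_runs=gbs_runs,
        families=families,
        family_truths=family_truths,
        populations=populations,
        sdy_candidates=sdy,
        config=config,
    )


def design_panel(
    data: StudyData,
    selection: Optional[SelectionConfig] = None,
    conversion_scores: Optional[Mapping[str, tuple[float, str]]] = None,
) -> tuple[PanelManifest, dict]:
    """Run the candidate-to-manifest path and return the manifest plus a
    per-stage audit (counts in / dropped / retained at every step)."""
    cfg = data.config
    selection = selection or SelectionConfig(
        budget=cfg.budget,
        rare_spacing=cfg.rare_spacing,
        common_spacing=cfg.common_spacing,
    )
    audit: dict = {}

    # --- family and population QC on the GBS markers
    family_report = qc.family_qc(data.families)
    pop_reports = {
        g: qc.filter_population_maf(p) for g, p in data.populations.items()
    }
    audit["family_qc"] = family_report.counts

    # --- per-record quality filters for the high-coverage set (both stages)
    highcov = data.callsets["highcov"]
    initial = qc.filter_highcov(highcov, "initial")
    highcov_initial = [c for c in highcov if c.id in initial.passed]
    design_stage = qc.filter_highcov(highcov_initial, "design")
    highcov_design = [c for c in highcov_initial if c.id in design_stage.passed]
    audit["highcov"] = {
        "n_in": len(highcov),
        "n_after_initial": len(highcov_initial),
        "n_after_design": len(highcov_design),
    }

    # --- alignment uniqueness for the short-tag platforms
    def uniquely_placed(cands: Sequence[CandidateSNP]) -> list[CandidateSNP]:
        return [
            c
            for c in cands
            if len(c.tag_sequence) >= 20
            and qc.count_genome_placements(c.tag_sequence, data.genome) == 1
        ]

    gbs_unique = uniquely_placed(data.callsets["gbs"])
    rnaseq_unique = uniquely_placed(data.callsets["rnaseq"])
    audit["alignment_uniqueness"] = {
        "gbs": {"n_in": len(data.callsets["gbs"]), "n_unique": len(gbs_unique)},
        "rnaseq": {
            "n_in": len(data.callsets["rnaseq"]),
            "n_unique": len(rnaseq_unique),
        },
    }

    # --- GBS markers surviving the family-based filters
    family_pass = family_report.passed | family_report.not_testable
    gbs_qced = [
        c for c in gbs_unique
        if _marker_id(c) in family_pass or _marker_id(c) not in set(family_report.table.index)
    ]

    # --- cross-platform validation (highcov against each smaller set)
    crossvals = [
        cross_validate(highcov_design, gbs_qced),
        cross_validate(highcov_design, data.callsets["rad"]),
        cross_validate(highcov_design, rnaseq_unique),
    ]
    audit["cross_validation"] = {
        "x".join(r.platform_pair): r.n_matches for r in crossvals
    }

    # --- GBS priority criteria
    # a SNP counts as detected in a population when the population's
    # genotypes actually show the alternate allele
    presence = {
        g: {
            m
            for m in p.markers
            if p.genotypes.loc[m].isin(["ab", "bb"]).any()
        }
        for g, p in data.populations.items()
    }
    fam_segregating = {
        fam.family_id: segregating_markers(fam.parents, None) & family_pass
        for fam in data.families
    }
    gbs_by_marker = {_marker_id(c): c for c in gbs_qced}
    selected = gbs_priority_select(pop_reports, presence, fam_segregating)
    gbs_selected = {
        m: gbs_by_marker[m] for m in selected if m in gbs_by_marker
    }
    audit["gbs_priority"] = {
        "n_selected": len(gbs_selected),
        "criteria": {k: sum(1 for v in selected.values() if k in v) for k in "abc"},
    }

    # --- tier 1: union, strand-ambiguity screen (Icelandic GBS exempt)
    tier1, tier1_audit = build_high_priority_tier(
        crossvals, gbs_selected, ambiguity_exempt_sources=()
    )
    audit["tier1"] = tier1_audit

    # --- high-coverage pools: transcript labels, flanks, ambiguity, AF strata
    label_in_transcript(highcov_design, data.annotation)
    ambiguity_report = qc.exclude_transcript_ambiguity(highcov_design)
    pool = [
        c for c in highcov_design
        if c.id in ambiguity_report.passed
        and qc.check_flank_length(c, 35)
        and not qc.is_strand_ambiguous(c.ref, c.alt)
    ]
    tier1_keys = {(c.seq_name, c.pos) for c in tier1}
    pool = [c for c in pool if (c.seq_name, c.pos) not in tier1_keys]
    rare_pool = [c for c in pool if classify_af(c.af, selection) == RARE]
    common_intergenic = [
        c for c in pool
        if classify_af(c.af, selection) == COMMON and not c.in_transcript
    ]
    audit["highcov_pools"] = {
        "n_pool": len(pool),
        "n_rare": len(rare_pool),
        "n_common_intergenic": len(common_intergenic),
    }

    # --- filler: putative markers that aligned but were never validated
    validated_keys = tier1_keys | {(c.seq_name, c.pos) for c in pool}
    filler = [
        c for c in (gbs_unique + rnaseq_unique)
        if (c.seq_name, c.pos) not in validated_keys
    ]
    # dedup filler against itself on placement
    seen: set[tuple[str, int]] = set()
    filler_unique = []
    for c in filler:
        if (c.seq_name, c.pos) not in seen:
            seen.add((c.seq_name, c.pos))
            filler_unique.append(c)
    audit["filler"] = {"n_filler": len(filler_unique)}

    manifest = assemble_panel(
        tier1=tier1,
        sdy=data.sdy_candidates,
        highcov_rare=rare_pool,
        highcov_common_intergenic=common_intergenic,
        filler_pool=filler_unique,
        genome=data.genome,
        config=selection,
        conversion_scores=conversion_scores,
    )
    audit["assembly"] = {
        k: v for k, v in manifest.audit.items() if k != "dropped"
    }
    return manifest, audit


def evaluate_panel(
    data: StudyData,
    manifest: PanelManifest,
    seed: int = 0,
    sex_per_group: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict:
    """Simulate genotyping of the designed array in every group and
    compute classification, sharing, coverage and sexing reports."""
    cfg = data.config
    sdy_ids = [
        m for m, p in zip(manifest.table["marker_id"], manifest.table["platform"])
        if p == "sdy"
    ]
    group_afs = {
        g: {
            row.marker_id: data.truth_by_pos[(row.seq_name, row.pos)].group_afs.get(g, 0.0)
            if (row.seq_name, row.pos) in data.truth_by_pos
            else 0.0
            for row in manifest.table.itertuples(index=False)
        }
        for g in cfg.groups
    }
    callsets = {}
    classifications = {}
    summaries = {}
    poly_sets = {}
    for j, group in enumerate(cfg.groups):
        sex = sex_per_group.get(group) if sex_per_group else None
        cs = simulate_array_run(
            manifest,
            group_afs,
            n_samples=cfg.n_test_samples,
            group=group,
            marker_failure_rate=cfg.marker_failure_rate,
            sample_call_rate_distribution=cfg.sample_call_rate_distribution,
            sdy_marker_ids=sdy_ids,
            sex_per_sample=sex,
            seed=seed + 100 + j,
        )
        cs, sample_qc = evaluate.apply_sample_qc(cs)
        classification = evaluate.classify_callset(cs)
        callsets[group] = cs
        classifications[group] = classification
        summaries[group] = {**evaluate.summarize_group(classification), **sample_qc}
        poly_sets[group] = classification.polymorphic()
    sharing = evaluate.venn_sharing(poly_sets)
    coverage = evaluate.coverage_report(manifest, data.genome, data.annotation,
                                        window=50_000)
    sex_tables = {
        g: evaluate.predict_sex(callsets[g], sdy_ids) for g in cfg.groups
    }
    concordance = {
        g: evaluate.sex_concordance(t) for g, t in sex_tables.items()
    }
    return {
        "callsets": callsets,
        "classifications": classifications,
        "summaries": summaries,
        "sharing": sharing,
        "coverage": coverage,
        "sex_tables": sex_tables,
        "sex_concordance_pct": concordance,
        "sdy_marker_ids": sdy_ids,
    }


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (paths + knobs)."""

    genome_fasta: str
    annotation_gff3: str
    candidate_vcfs: Mapping[str, str]  # platform -> path
    family_tsvs: Sequence[str] = ()
    population_tsvs: Mapping[str, str] = field(default_factory=dict)
    output_dir: str = "out"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    max_missing: float = 0.5
    alpha: float = 0.01
    min_maf: float = 0.05
    seed: int = 0


def write_study(data: StudyData, out_dir: str) -> dict[str, str]:
    """Serialize a synthetic study to standard formats; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    paths["genome"] = os.path.join(out_dir, "genome.fasta")
    io.write_fasta(data.genome, paths["genome"])
    paths["annotation"] = os.path.join(out_dir, "genes.gff3")
    io.write_gff3(data.annotation, paths["annotation"])
    for platform, calls in data.callsets.items():
        p = os.path.join(out_dir, f"candidates_{platform}.vcf")
        io.write_vcf(calls, p, genome=data.genome)
        paths[f"vcf_{platform}"] = p
    for fam in data.families:
        p = os.path.join(out_dir, f"family_{fam.family_id}.tsv")
        io.write_family_genotypes(fam, p)
        paths[f"family_{fam.family_id}"] = p
    for group, pop in data.populations.items():
        p = os.path.join(out_dir, f"population_{group}.tsv")
        io.write_population_genotypes(pop, p)
        paths[f"population_{group}"] = p
    return paths


def run_pipeline(
    config: StudyConfig = StudyConfig(),
    seed: int = 0,
    out_dir: Optional[str] = None,
) -> dict:
    """Full synthetic run: simulate the study, design the panel, evaluate
    it, and (optionally) write every artifact plus an audit log under
    ``out_dir``. Deterministic for a fixed config and seed."""
    data = simulate_study(config, seed=seed)
    manifest, audit = design_panel(data)
    results = evaluate_panel(data, manifest, seed=seed)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_study(data, os.path.join(out_dir, "inputs"))
        io.write_manifest_tsv(manifest, os.path.join(out_dir, "manifest.tsv"))
        io.write_manifest_vcf(
            manifest, os.path.join(out_dir, "manifest.vcf"), genome=data.genome
        )
        sharing = results["sharing"]
        sharing.per_group.to_csv(
            os.path.join(out_dir, "sharing.tsv"), sep="\t", index_label="group"
        )
        results["coverage"].per_chromosome.to_csv(
            os.path.join(out_dir, "coverage.tsv"), sep="\t", index_label="chromosome"
        )
        for g, t in results["sex_tables"].items():
            t.to_csv(os.path.join(out_dir, f"sex_{g}.tsv"), sep="\t",
                     index_label="sample")
        with open(os.path.join(out_dir, "audit.json"), "w") as fh:
            json.dump(
                {
                    "audit": audit,
                    "summaries": results["summaries"],
                    "sex_concordance_pct": results["sex_concordance_pct"],
                    "seed": seed,
                },
                fh,
                indent=2,
                default=str,
            )
    return {
        "data": data,
        "manifest": manifest,
        "audit": audit,
        **results,
    }
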