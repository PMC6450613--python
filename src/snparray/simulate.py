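"""Seeded generators for every input the design pipeline consumes.

The generators emulate a small multi-chromosome genome with unplaced
contigs, true SNPs with a configurable allele-frequency spectrum,
platform-specific candidate call sets (shared true SNPs plus
platform-private false positives), full-sib family genotypes with injected
Mendelian errors / missingness / segregation distortion, and a simulated
post-design array genotyping run across multiple groups.

Every function takes an explicit integer ``seed``; identical seeds give
byte-identical outputs. Read-level simulation (FASTQ, sequencing error)
and linkage disequilibrium between markers are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    CandidateSNP,
    FamilyGenotypes,
    GeneAnnotation,
    GeneRecord,
    GenomeAssembly,
    GenotypeCallSet,
    InvalidInputError,
    PanelManifest,
    PlatformProfile,
    TrueVariant,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def sample_distribution(
    spec: tuple, rng: np.random.Generator, size: Optional[int] = None
):
    """Draw from a named distribution spec.

    Supported: ``("point", v)``, ``("uniform", lo, hi)``,
    ``("normal", mu, sd)``, ``("lognormal", mu, sigma)``,
    ``("beta", a, b)``.
    """
    family, *params = spec
    if family == "point":
        v = params[0]
        return v if size is None else np.full(size, v, dtype=float)
    if family == "uniform":
        return rng.uniform(params[0], params[1], size=size)
    if family == "normal":
        return rng.normal(params[0], params[1], size=size)
    if family == "lognormal":
        return rng.lognormal(params[0], params[1], size=size)
    if family == "beta":
        return rng.beta(params[0], params[1], size=size)
    raise InvalidInputError(f"unknown distribution family {family!r}")


def generate_genome(
    n_chromosomes: int,
    chromosome_length: int,
    n_contigs: int = 0,
    contig_length_range: tuple[int, int] = (1_000, 10_000),
    seed: int = 0,
) -> GenomeAssembly:
    """Random genome with ``n_chromosomes`` equal-length chromosomes and
    ``n_contigs`` unplaced contigs of uniform-random length."""
    if n_chromosomes < 0 or n_contigs < 0:
        raise InvalidInputError("counts must be non-negative")
    if n_chromosomes == 0 and n_contigs == 0:
        raise InvalidInputError("genome needs at least one sequence")
    if n_chromosomes == 0:
        raise InvalidInputError("assembly needs at least one chromosome")
    if chromosome_length < 100:
        raise InvalidInputError("chromosome_length must be >= 100 bp")
    if n_contigs and (contig_length_range[0] < 100):
        raise InvalidInputError("contig lengths must be >= 100 bp")

    rng = _rng(seed)
    width = max(2, len(str(n_chromosomes)))
    sequences: dict[str, str] = {}
    is_chromosome: dict[str, bool] = {}
    for i in range(n_chromosomes):
        name = f"chr{i + 1:0{width}d}"
        sequences[name] = _random_dna(rng, chromosome_length)
        is_chromosome[name] = True
    cwidth = max(3, len(str(n_contigs)))
    lo, hi = contig_length_range
    for i in range(n_contigs):
        name = f"contig{i + 1:0{cwidth}d}"
        sequences[name] = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        is_chromosome[name] = False
    return GenomeAssembly(sequences=sequences, is_chromosome=is_chromosome)


def generate_annotation(
    genome: GenomeAssembly,
    genes_per_mb: float = 20.0,
    gene_length_range: tuple[int, int] = (500, 5_000),
    seed: int = 0,
) -> GeneAnnotation:
    """Non-overlapping gene intervals dropped uniformly on chromosomes."""
    rng = _rng(seed)
    records: list[GeneRecord] = []
    idx = 1
    for name in genome.chromosomes:
        length = len(genome.sequences[name])
        n_genes = rng.poisson(genes_per_mb * length / 1e6)
        pos = 1
        for _ in range(n_genes):
            glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            gap = int(rng.integers(100, max(101, length // max(n_genes, 1))))
            start = pos + gap
            end = start + glen - 1
            if end > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(GeneRecord(f"gene{idx:05d}", name, start, end, strand))
            idx += 1
            pos = end
    return GeneAnnotation(records=records)


def generate_true_variants(
    genome: GenomeAssembly,
    density_per_kb: float,
    af_distribution: tuple = ("beta", 0.8, 0.8),
    groups: Sequence[str] = ("groupA",),
    af_correlation: float = 0.0,
    seed: int = 0,
) -> list[TrueVariant]:
    """Plant true SNPs at unique positions at ``density_per_kb``.

    Per-group alternate-allele frequencies are drawn independently from
    ``af_distribution`` unless ``af_correlation`` is set, in which case
    each group's AF equals a shared draw with that probability.
    """
    if density_per_kb <= 0:
        raise InvalidInputError("density must be positive")
    rng = _rng(seed)
    variants: list[TrueVariant] = []
    for name in sorted(genome.sequences):
        seq = genome.sequences[name]
        length = len(seq)
        n = rng.binomial(length, min(1.0, density_per_kb / 1000.0))
        if n > length:
            raise InvalidInputError("density too high for unique positions")
        positions = np.sort(rng.choice(length, size=n, replace=False)) + 1
        for pos in positions:
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            shared = float(np.clip(sample_distribution(af_distribution, rng), 0, 1))
            afs = {}
            for g in groups:
                if rng.random() < af_correlation:
                    afs[g] = shared
                else:
                    afs[g] = float(
                        np.clip(sample_distribution(af_distribution, rng), 0, 1)
                    )
            variants.append(
                TrueVariant(seq_name=name, pos=int(pos), ref=ref, alt=alt, group_afs=afs)
            )
    return variants


def _flanks(genome: GenomeAssembly, name: str, pos: int, flank: int) -> tuple[str, str]:
    left = genome.subseq(name, pos - flank, pos - 1)
    right = genome.subseq(name, pos + 1, pos + flank)
    return left, right


def simulate_platform_callset(
    truth: Sequence[TrueVariant],
    genome: GenomeAssembly,
    profile: PlatformProfile,
    seed: int = 0,
) -> list[CandidateSNP]:
    """Emit one platform's candidate call set: each true SNP detected with
    ``profile.detection_prob``, plus uniform false positives at
    ``profile.fp_rate_per_kb``; AF estimates are binomial resamples of the
    truth at the profile's sample size."""
    rng = _rng(seed)
    group = profile.af_group
    calls: list[CandidateSNP] = []
    truth_positions: dict[str, set[int]] = {}
    for v in truth:
        truth_positions.setdefault(v.seq_name, set()).add(v.pos)

    def quality_draws() -> dict[str, Optional[float]]:
        out: dict[str, Optional[float]] = {}
        for key in ("DP", "QUAL", "GQ", "MQ"):
            spec = profile.quality_distributions.get(key)
            out[key] = None if spec is None else float(sample_distribution(spec, rng))
        return out

    n2 = 2 * profile.af_sample_size
    for v in truth:
        if rng.random() >= profile.detection_prob:
            continue
        left, right = _flanks(genome, v.seq_name, v.pos, profile.flank_length)
        true_af = v.group_afs.get(group or next(iter(v.group_afs), ""), 0.5)
        est_af = rng.binomial(n2, true_af) / n2
        q = quality_draws()
        calls.append(
            CandidateSNP(
                # placement-derived id: identical re-detections of one
                # variant (e.g. the two read-trim runs) share an id
                id=f"{profile.name}_{v.seq_name}_{v.pos}_{v.alt}",
                platform=profile.name,
                seq_name=v.seq_name,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                left_flank=left,
                right_flank=right,
                af=float(est_af),
                dp=q["DP"],
                qual=q["QUAL"],
                gq=q["GQ"],
                mq=q["MQ"],
            )
        )
    # platform-private false positives at non-variant positions
    for name in sorted(genome.sequences):
        seq = genome.sequences[name]
        n_fp = rng.poisson(profile.fp_rate_per_kb * len(seq) / 1000.0)
        taken = truth_positions.get(name, set())
        placed = 0
        while placed < n_fp:
            pos = int(rng.integers(1, len(seq) + 1))
            if pos in taken:
                continue
            taken.add(pos)
            placed += 1
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            left, right = _flanks(genome, name, pos, profile.flank_length)
            q = quality_draws()
            calls.append(
                CandidateSNP(
                    id=f"{profile.name}_{name}_{pos}_{alt}",
                    platform=profile.name,
                    seq_name=name,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    left_flank=left,
                    right_flank=right,
                    af=float(rng.uniform(0.0, 0.5)),
                    dp=q["DP"],
                    qual=q["QUAL"],
                    gq=q["GQ"],
                    mq=q["MQ"],
                )
            )
    calls.sort(key=lambda c: (c.seq_name, c.pos, c.id))
    return calls


# ---------------------------------------------------------------------------
# Family simulation

_ALLELES = {"aa": ("a", "a"), "ab": ("a", "b"), "bb": ("b", "b")}


def mendelian_class_probs(p1: str, p2: str) -> dict[str, float]:
    """Expected progeny genotype probabilities for a parent pair."""
    probs: dict[str, float] = {}
    for a1 in _ALLELES[p1]:
        for a2 in _ALLELES[p2]:
            g = "".join(sorted(a1 + a2))
            probs[g] = probs.get(g, 0.0) + 0.25
    return probs


def tilt_probs(probs: Mapping[str, float], strength: float) -> dict[str, float]:
    """Exponentially tilt Mendelian class probabilities toward the ``b``
    allele: class weight multiplied by exp(strength * #b alleles). Nests
    the Mendelian null at strength 0."""
    w = {g: p * float(np.exp(strength * g.count("b"))) for g, p in probs.items()}
    z = sum(w.values())
    return {g: v / z for g, v in w.items()}


def draw_parents_hwe(
    truth: Sequence[TrueVariant],
    group: str,
    marker_ids: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> dict[str, tuple[str, str]]:
    """Draw two parents per marker under Hardy-Weinberg at the group AF."""
    rng = _rng(seed)
    ids = marker_ids or [f"{v.seq_name}:{v.pos}" for v in truth]
    cross: dict[str, tuple[str, str]] = {}
    for mid, v in zip(ids, truth):
        q = v.group_afs.get(group, 0.5)
        gt_probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        g1, g2 = rng.choice(["aa", "ab", "bb"], size=2, p=gt_probs)
        cross[mid] = (str(g1), str(g2))
    return cross


@dataclass
class FamilyTruth:
    """Ground-truth labels returned next to a simulated family."""

    distorted_markers: set[str] = field(default_factory=set)
    error_cells: set[tuple[str, str]] = field(default_factory=set)
    distortion_strength: float = 0.0


def simulate_family(
    cross: Mapping[str, tuple[str, str]],
    n_progeny: int,
    family_id: str = "fam1",
    mendelian_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    distorted_fraction: float = 0.0,
    distortion_strength: float = 1.0,
    seed: int = 0,
) -> tuple[FamilyGenotypes, FamilyTruth]:
    """Simulate progeny genotypes for a cross design.

    Non-distorted markers segregate per Mendelian expectation; a
    ``distorted_fraction`` of markers has class probabilities
    exponentially tilted by ``distortion_strength``. Genotyping errors
    (replacement by a different uniformly-chosen genotype) and
    missingness are injected independently per cell; the returned
    :class:`FamilyTruth` labels distorted markers and error cells.
    """
    for rate in (mendelian_error_rate, missing_rate, distorted_fraction):
        if not 0.0 <= rate <= 1.0:
            raise InvalidInputError("rates must be within [0, 1]")
    if n_progeny < 1:
        raise InvalidInputError("n_progeny must be >= 1")
    rng = _rng(seed)
    markers = list(cross)
    progeny_ids = [f"{family_id}_p{j + 1:03d}" for j in range(n_progeny)]
    n_distorted = int(round(distorted_fraction * len(markers)))
    distorted = set(
        rng.choice(markers, size=n_distorted, replace=False) if n_distorted else []
    )
    truth = FamilyTruth(
        distorted_markers=set(distorted), distortion_strength=distortion_strength
    )
    data = {}
    codes = np.array(["aa", "ab", "bb"])
    for m in markers:
        probs = mendelian_class_probs(*cross[m])
        if m in distorted:
            probs = tilt_probs(probs, distortion_strength)
        classes = list(probs)
        draws = rng.choice(classes, size=n_progeny, p=[probs[c] for c in classes])
        row = list(map(str, draws))
        for j in range(n_progeny):
            if mendelian_error_rate and rng.random() < mendelian_error_rate:
                alternatives = codes[codes != row[j]]
                row[j] = str(rng.choice(alternatives))
                truth.error_cells.add((m, progeny_ids[j]))
        for j in range(n_progeny):
            if missing_rate and rng.random() < missing_rate:
                row[j] = MISSING
        data[m] = row
    frame = pd.DataFrame.from_dict(
        data, orient="index", columns=progeny_ids
    ).reindex(markers)
    fam = FamilyGenotypes(family_id=family_id, parents=dict(cross), progeny=frame)
    return fam, truth


def simulate_population(
    truth: Sequence[TrueVariant],
    group: str,
    n_samples: int,
    missing_rate: float = 0.0,
    marker_ids: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> PopulationGenotypes:
    """Hardy-Weinberg genotypes for unrelated samples of one group."""
    from .model import PopulationGenotypes

    rng = _rng(seed)
    ids = marker_ids or [f"{v.seq_name}:{v.pos}" for v in truth]
    sample_ids = [f"{group}_s{j + 1:03d}" for j in range(n_samples)]
    rows = {}
    for mid, v in zip(ids, truth):
        q = v.group_afs.get(group, 0.0)
        gts = rng.choice(
            ["aa", "ab", "bb"],
            size=n_samples,
            p=[(1 - q) ** 2, 2 * q * (1 - q), q**2],
        )
        gts = [MISSING if rng.random() < missing_rate else str(g) for g in gts]
        rows[mid] = gts
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return PopulationGenotypes(group=group, genotypes=frame)


# ---------------------------------------------------------------------------
# Post-design array run


def simulate_array_run(
    panel: PanelManifest,
    group_afs: Mapping[str, Mapping[str, float]],
    n_samples: int,
    group: str,
    marker_failure_rate: float = 0.0,
    failed_marker_nocall_rate: float = 0.9,
    sample_call_rate_distribution: tuple = ("point", 1.0),
    sdy_marker_ids: Sequence[str] = (),
    sex_per_sample: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> GenotypeCallSet:
    """Simulate one group's genotyping session on the designed panel.

    Genotypes are Hardy-Weinberg draws at the group's per-marker AF;
    a ``marker_failure_rate`` fraction of markers fails and emits
    no-calls at ``failed_marker_nocall_rate``; each sample has a target
    call rate drawn from ``sample_call_rate_distribution`` (baseline
    no-call probability 1 - rate). Markers listed in ``sdy_marker_ids``
    model the male-limited sex gene: called (presence) in males only,
    no-call in females.
    """
    afs = group_afs[group]
    panel_ids = set(panel.marker_ids)
    unknown = set(afs) - panel_ids
    if unknown:
        raise InvalidInputError(f"group AFs for markers not on panel: {sorted(unknown)[:3]}")
    unknown_sdy = set(sdy_marker_ids) - panel_ids
    if unknown_sdy:
        raise InvalidInputError(f"unknown sdY marker ids: {sorted(unknown_sdy)}")
    rng = _rng(seed)
    sample_ids = [f"{group}_t{j + 1:04d}" for j in range(n_samples)]
    if sex_per_sample is None:
        sex = [str(s) for s in rng.choice(["M", "F"], size=n_samples)]
    else:
        if len(sex_per_sample) != n_samples:
            raise InvalidInputError("sex_per_sample length != n_samples")
        sex = list(sex_per_sample)
    target_rates = np.clip(
        np.asarray(
            sample_distribution(sample_call_rate_distribution, rng, size=n_samples),
            dtype=float,
        ),
        0.0,
        1.0,
    )
    sdy = set(sdy_marker_ids)
    markers = panel.marker_ids
    failed = {m for m in markers if m not in sdy and rng.random() < marker_failure_rate}
    rows = {}
    for m in markers:
        if m in sdy:
            # presence/absence: males yield a call, females a no-call
            rows[m] = ["aa" if s == "M" else MISSING for s in sex]
            continue
        q = afs.get(m, 0.0)
        gts = rng.choice(
            ["aa", "ab", "bb"],
            size=n_samples,
            p=[(1 - q) ** 2, 2 * q * (1 - q), q**2],
        )
        nocall_p = np.full(n_samples, 1.0 - target_rates)
        if m in failed:
            nocall_p = np.maximum(nocall_p, failed_marker_nocall_rate)
        drop = rng.random(n_samples) < nocall_p
        rows[m] = [MISSING if d else str(g) for g, d in zip(gts, drop)]
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids).reindex(
        markers
    )
    observed_rate = (calls != MISSING).mean(axis=0)
    samples = pd.DataFrame(
        {"sex": sex, "call_rate": observed_rate.values}, index=sample_ids
    )
    return GenotypeCallSet(group=group, samples=samples, calls=calls)
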