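"""Core domain types for array design and evaluation.

Coordinate convention: all genomic positions are 1-based and intervals are
inclusive at both ends (VCF/GFF convention). Genotypes at biallelic markers
are coded ``aa`` (homozygous reference), ``ab`` (heterozygous), ``bb``
(homozygous alternate) and ``--`` (missing / no-call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

DNA_ALPHABET = frozenset("ACGT")
GENOTYPE_CODES = ("aa", "ab", "bb")
MISSING = "--"
VALID_CODES = frozenset(GENOTYPE_CODES) | {MISSING}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented type invariant."""


@dataclass
class GenomeAssembly:
    """A reference assembly: named sequences split into chromosomes and
    unplaced contigs. Serves as the coordinate frame for every other object.
    """

    sequences: Mapping[str, str]
    is_chromosome: Mapping[str, bool]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise InvalidInputError("assembly has no sequences")
        if set(self.sequences) != set(self.is_chromosome):
            raise InvalidInputError("sequence names and chromosome flags disagree")
        for name, seq in self.sequences.items():
            if not seq:
                raise InvalidInputError(f"sequence {name!r} is empty")
            if not DNA_ALPHABET.issuperset(seq):
                raise InvalidInputError(f"sequence {name!r} has non-ACGT characters")
        if not any(self.is_chromosome.values()):
            raise InvalidInputError("assembly must contain at least one chromosome")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return [n for n, flag in self.is_chromosome.items() if flag]

    @property
    def contigs(self) -> list[str]:
        return [n for n, flag in self.is_chromosome.items() if not flag]

    def base(self, name: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[name][pos - 1]

    def subseq(self, name: str, start: int, end: int) -> str:
        """Inclusive 1-based slice, truncated at sequence ends."""
        seq = self.sequences[name]
        return seq[max(start, 1) - 1 : min(end, len(seq))]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    seq_name: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class GeneAnnotation:
    """Gene models as simple inclusive intervals on assembly sequences."""

    records: Sequence[GeneRecord]

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise InvalidInputError("gene_ids are not unique")
        for r in self.records:
            if not (1 <= r.start <= r.end):
                raise InvalidInputError(
                    f"gene {r.gene_id}: invalid interval [{r.start}, {r.end}]"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class TrueVariant:
    """Ground-truth SNP used by the simulator; carries the true per-group
    population allele frequency of the alternate allele."""

    seq_name: str
    pos: int
    ref: str
    alt: str
    group_afs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InvalidInputError("ref and alt alleles must differ")
        for g, af in self.group_afs.items():
            if not 0.0 <= af <= 1.0:
                raise InvalidInputError(f"AF for group {g} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int]:
        return (self.seq_name, self.pos)


@dataclass
class PlatformProfile:
    """Statistical sketch of one SNP discovery platform.

    ``detection_prob`` is the per-true-SNP probability the platform calls
    it; ``fp_rate_per_kb`` places platform-private false positives; the
    quality distributions supply per-record DP/QUAL/GQ/MQ draws, given as
    ``{"DP": ("normal", mu, sd), ...}`` (supported families: ``point``,
    ``uniform``, ``normal``, ``lognormal``). ``af_sample_size`` is the
    number of diploid individuals behind the platform's AF estimate.
    """

    name: str
    detection_prob: float
    fp_rate_per_kb: float
    flank_length: int
    quality_distributions: Mapping[str, tuple] = field(default_factory=dict)
    af_sample_size: int = 8
    af_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise InvalidInputError("detection_prob outside [0, 1]")
        if self.fp_rate_per_kb < 0:
            raise InvalidInputError("fp_rate_per_kb negative")
        if self.flank_length < 0:
            raise InvalidInputError("flank_length negative")
        if self.af_sample_size < 1:
            raise InvalidInputError("af_sample_size must be >= 1")


@dataclass
class CandidateSNP:
    """One putative variant from one discovery platform."""

    id: str
    platform: str
    seq_name: str
    pos: int
    ref: str
    alt: str
    left_flank: str = ""
    right_flank: str = ""
    af: Optional[float] = None
    dp: Optional[float] = None
    qual: Optional[float] = None
    gq: Optional[float] = None
    mq: Optional[float] = None
    in_transcript: Optional[bool] = None
    transcript_id: Optional[str] = None
    source_contig: Optional[str] = None
    tier: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InvalidInputError(f"candidate {self.id}: ref == alt")
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise InvalidInputError(f"candidate {self.id}: AF outside [0, 1]")
        for flank in (self.left_flank, self.right_flank):
            if flank and not DNA_ALPHABET.issuperset(flank):
                raise InvalidInputError(f"candidate {self.id}: non-ACGT flank")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.ref, self.alt))

    @property
    def tag_sequence(self) -> str:
        """Flanks with the reference allele in place — the duplicate key."""
        return self.left_flank + self.ref + self.right_flank


def _validate_genotype_frame(df: pd.DataFrame, what: str) -> None:
    bad = set(df.values.ravel()) - VALID_CODES
    if bad:
        raise InvalidInputError(f"{what}: invalid genotype codes {sorted(bad)}")


@dataclass
class FamilyGenotypes:
    """One family: parental genotypes per marker and a progeny genotype
    matrix (markers x progeny)."""

    family_id: str
    parents: Mapping[str, tuple[str, str]]
    progeny: pd.DataFrame

    def __post_init__(self) -> None:
        if self.progeny.shape[1] < 1:
            raise InvalidInputError(f"family {self.family_id}: no progeny")
        _validate_genotype_frame(self.progeny, f"family {self.family_id}")
        for marker, (g1, g2) in self.parents.items():
            for g in (g1, g2):
                if g not in VALID_CODES:
                    raise InvalidInputError(
                        f"family {self.family_id}, marker {marker}: "
                        f"unknown parent genotype {g!r}"
                    )

    @property
    def markers(self) -> list[str]:
        return list(self.progeny.index)

    @property
    def n_progeny(self) -> int:
        return self.progeny.shape[1]


@dataclass
class PopulationGenotypes:
    """Unrelated-sample genotype matrix (markers x samples) for one group."""

    group: str
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_genotype_frame(self.genotypes, f"population {self.group}")

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.index)


PASS = "pass"
FAIL = "fail"
NOT_TESTABLE = "not_testable"


@dataclass
class FilterReport:
    """Per-marker outcome of one QC rule.

    ``table`` is indexed by marker id with at least ``status`` and
    ``reason`` columns; rule-specific statistics (maf, chi2, pvalue,
    missing_fraction, ...) ride along as extra columns.
    """

    rule: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "status" not in self.table.columns:
            raise InvalidInputError("FilterReport table needs a 'status' column")
        if self.table.index.has_duplicates:
            raise InvalidInputError("FilterReport has duplicated marker ids")

    @property
    def passed(self) -> set[str]:
        return set(self.table.index[self.table["status"] == PASS])

    @property
    def failed(self) -> set[str]:
        return set(self.table.index[self.table["status"] == FAIL])

    @property
    def not_testable(self) -> set[str]:
        return set(self.table.index[self.table["status"] == NOT_TESTABLE])

    @property
    def counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()


@dataclass
class CrossValidationResult:
    """Pairs of candidates confirmed across two platforms, plus the
    deduplicated union of validated candidates with their evidence sets."""

    pairs: list[tuple[str, str]]
    platform_pair: tuple[str, str]
    validated: list[CandidateSNP]
    evidence: Mapping[str, set[str]]
    skipped_multiallelic: int = 0

    @property
    def n_matches(self) -> int:
        return len(self.pairs)


@dataclass
class SelectionConfig:
    """Knobs of the panel assembly.

    AF strata follow array-design practice: *rare* [0.05, 0.15) and
    *common* [0.15, 0.85]; the rare stratum is thinned to ~900 kb
    spacing, the common intergenic stratum to ~62 kb. Probes are 71-mers
    with the variant at base 36 (and a long 101-mer form, variant at 51,
    used for transcript comparison).
    """

    budget: int = 87_000
    rare_af_bounds: tuple[float, float] = (0.05, 0.15)
    common_af_bounds: tuple[float, float] = (0.15, 0.85)
    rare_spacing: int = 900_000
    common_spacing: int = 62_000
    probe_length: int = 71
    snp_offset: int = 36
    long_probe_length: int = 101
    long_snp_offset: int = 51
    spacing_mode: str = "window"

    def __post_init__(self) -> None:
        if self.rare_af_bounds[1] != self.common_af_bounds[0]:
            raise InvalidInputError("rare upper bound must equal common lower bound")
        if not 1 <= self.snp_offset <= self.probe_length:
            raise InvalidInputError("snp_offset outside probe")
        if self.spacing_mode not in ("window", "greedy"):
            raise InvalidInputError("spacing_mode must be 'window' or 'greedy'")


TIER_HIGH_PRIORITY = 1
TIER_SDY = 2
TIER_HIGHCOV = 3
TIER_FILLER = 4

MANIFEST_COLUMNS = [
    "marker_id",
    "seq_name",
    "pos",
    "ref",
    "alt",
    "tier",
    "reason",
    "in_transcript",
    "probe",
    "platform",
    "score",
]


@dataclass
class PanelManifest:
    """The designed array: one row per selected marker."""

    table: pd.DataFrame
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"manifest missing columns {sorted(missing)}")
        if self.table["marker_id"].duplicated().any():
            raise InvalidInputError("manifest has duplicate marker ids")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])


@dataclass
class GenotypeCallSet:
    """Post-design genotyping output for one group.

    ``samples`` is indexed by sample id with columns ``sex`` (M/F/empty)
    and ``call_rate``; ``calls`` is markers x samples.
    """

    group: str
    samples: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_genotype_frame(self.calls, f"callset {self.group}")
        if not self.samples["call_rate"].between(0, 1).all():
            raise InvalidInputError("sample call rates outside [0, 1]")
        if list(self.calls.columns) != list(self.samples.index):
            raise InvalidInputError("calls columns and sample index disagree")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)


# Axiom-style marker categories
POLY_HIGH_RES = "PolyHighRes"
NO_MINOR_HOM = "NoMinorHom"
MONO_HIGH_RES = "MonoHighRes"
CALL_RATE_BELOW = "CallRateBelowThreshold"
OTHER = "NotRecommended-Other"

CATEGORIES = (POLY_HIGH_RES, NO_MINOR_HOM, MONO_HIGH_RES, CALL_RATE_BELOW, OTHER)
POLYMORPHIC_CATEGORIES = frozenset({POLY_HIGH_RES, NO_MINOR_HOM})
RECOMMENDED_CATEGORIES = frozenset({POLY_HIGH_RES, NO_MINOR_HOM, MONO_HIGH_RES})


@dataclass
class MarkerClassification:
    """Marker id -> category, with derived recommended/polymorphic flags."""

    categories: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = set(self.categories.values()) - set(CATEGORIES)
        if bad:
            raise InvalidInputError(f"unknown categories {sorted(bad)}")

    def recommended(self) -> set[str]:
        return {m for m, c in self.categories.items() if c in RECOMMENDED_CATEGORIES}

    def polymorphic(self) -> set[str]:
        return {m for m, c in self.categories.items() if c in POLYMORPHIC_CATEGORIES}

    def monomorphic(self) -> set[str]:
        return {m for m, c in self.categories.items() if c == MONO_HIGH_RES}


@dataclass
class SharingReport:
    """Cross-group sharing of polymorphic markers: per-group totals,
    unique/shared splits, and all 2^k - 1 Venn region counts."""

    per_group: pd.DataFrame
    venn_regions: Mapping[frozenset, int]
    union_size: int


@dataclass
class CoverageReport:
    """Genome coverage of the designed panel."""

    per_chromosome: pd.DataFrame
    empty_windows: list[tuple[str, int, int]]
    n_windows: int
    window_size: int
    n_contigs: int
    n_contigs_with_marker: int
    contig_fraction: float
    contig_sequence_fraction: float
    n_genes: int
    n_genes_with_marker: int
    gene_fraction: float
    n_on_chromosomes: int
    n_on_contigs: int
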