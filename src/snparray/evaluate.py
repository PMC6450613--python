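"""Post-genotyping evaluation: marker classification, cross-group
sharing, genome coverage, and genotypic sexing.

Marker categories follow array-genotyping practice: *polymorphic high
resolution* (both homozygote classes observed), *no minor homozygote*
(heterozygotes but no minor-allele homozygote), *monomorphic high
resolution* (one allele only), and call-rate failure. A marker is
*recommended* when it is not a call-rate failure; *polymorphic* covers
the first two categories. The surrogate classifier here uses only the
observed call rate and genotype classes; the proprietary
cluster-resolution metrics of commercial genotyping suites are not
re-derived.

Percentages are printed to one decimal with round-half-even.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .model import (
    CALL_RATE_BELOW,
    MISSING,
    MONO_HIGH_RES,
    NO_MINOR_HOM,
    POLY_HIGH_RES,
    CoverageReport,
    GeneAnnotation,
    GenomeAssembly,
    GenotypeCallSet,
    InvalidInputError,
    MarkerClassification,
    PanelManifest,
    SharingReport,
)


def round1(x: float) -> float:
    """Round to 1 decimal, half to even — the convention used for every
    percentage this package prints."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_EVEN))


def apply_sample_qc(
    callset: GenotypeCallSet,
    min_sample_call_rate: float = 0.97,
    min_mean_passing_call_rate: float = 0.98,
    dish_qc_pass: Optional[Mapping[str, bool]] = None,
) -> tuple[GenotypeCallSet, dict]:
    """Drop samples whose call rate does not *exceed* the threshold; flag
    the whole run when the mean call rate of passing samples does not
    exceed its threshold. Dish-QC, when supplied as a per-sample boolean,
    is applied first; otherwise it is skipped."""
    if len(callset.samples) == 0:
        raise InvalidInputError("empty callset")
    samples = callset.samples
    keep = samples["call_rate"] > min_sample_call_rate
    if dish_qc_pass is not None:
        dish = samples.index.map(lambda s: bool(dish_qc_pass.get(s, True)))
        keep &= dish
    passing = samples[keep]
    mean_rate = float(passing["call_rate"].mean()) if len(passing) else float("nan")
    run_passes = len(passing) > 0 and mean_rate > min_mean_passing_call_rate
    filtered = GenotypeCallSet(
        group=callset.group,
        samples=passing,
        calls=callset.calls[passing.index],
    )
    report = {
        "n_samples_in": len(samples),
        "n_samples_removed": int((~keep).sum()),
        "mean_passing_call_rate": mean_rate,
        "run_passes": bool(run_passes),
    }
    return filtered, report


def classify_marker(calls: Sequence[str], min_marker_call_rate: float = 0.97) -> str:
    """Classify one marker's call vector into its category."""
    if len(calls) == 0:
        raise InvalidInputError("no samples")
    called = [g for g in calls if g != MISSING]
    if len(called) / len(calls) < min_marker_call_rate:
        return CALL_RATE_BELOW
    observed = set(called)
    n_aa = sum(1 for g in called if g == "aa")
    n_bb = sum(1 for g in called if g == "bb")
    if observed <= {"aa"} or observed <= {"bb"}:
        return MONO_HIGH_RES
    if n_aa > 0 and n_bb > 0:
        return POLY_HIGH_RES
    if "ab" in observed:
        return NO_MINOR_HOM
    return POLY_HIGH_RES  # aa and bb without ab: both homozygote classes


def classify_callset(
    callset: GenotypeCallSet, min_marker_call_rate: float = 0.97
) -> MarkerClassification:
    categories = {
        m: classify_marker(list(callset.calls.loc[m]), min_marker_call_rate)
        for m in callset.markers
    }
    return MarkerClassification(categories=categories)


def summarize_group(classification: MarkerClassification) -> dict:
    """Per-group counts and the percentage of recommended markers that
    are polymorphic (1 decimal). With zero recommended markers the
    percentage is undefined (NaN), not 0."""
    recommended = classification.recommended()
    polymorphic = classification.polymorphic()
    monomorphic = classification.monomorphic()
    pct = (
        round1(100.0 * len(polymorphic) / len(recommended))
        if recommended
        else float("nan")
    )
    return {
        "n_recommended": len(recommended),
        "n_polymorphic": len(polymorphic),
        "n_monomorphic": len(monomorphic),
        "pct_polymorphic_of_recommended": pct,
    }


def venn_sharing(per_group: Mapping[str, Set[str]]) -> SharingReport:
    """Exact set algebra over per-group polymorphic marker sets: all
    2^k - 1 Venn region counts, per-group unique/shared splits, and
    unique percentages of each group's total."""
    if not per_group:
        raise InvalidInputError("at least one group required")
    groups = sorted(per_group)
    union: set[str] = set().union(*per_group.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(groups) + 1):
        for members in combinations(groups, r):
            inside = set.intersection(*(set(per_group[g]) for g in members))
            outside = set().union(
                *(set(per_group[g]) for g in groups if g not in members), set()
            )
            regions[frozenset(members)] = len(inside - outside)
    rows = {}
    for g in groups:
        total = len(per_group[g])
        unique = regions[frozenset([g])]
        shared = total - unique
        rows[g] = {
            "total_polymorphic": total,
            "unique_to_group": unique,
            "shared_with_others": shared,
            "pct_unique": round1(100.0 * unique / total) if total else float("nan"),
        }
    return SharingReport(
        per_group=pd.DataFrame.from_dict(rows, orient="index"),
        venn_regions=regions,
        union_size=len(union),
    )


def pairwise_sharing(
    per_group: Mapping[str, Set[str]], group_a: str, group_b: str
) -> dict:
    """Markers polymorphic in both groups as a percentage of the pair's
    union (1 decimal)."""
    a, b = set(per_group[group_a]), set(per_group[group_b])
    union, inter = a | b, a & b
    pct = round1(100.0 * len(inter) / len(union)) if union else float("nan")
    return {"n_union": len(union), "n_shared": len(inter), "pct_shared": pct}


def _normalize_genome(
    genome: Union[GenomeAssembly, tuple[Mapping[str, int], Mapping[str, bool]]],
) -> tuple[Mapping[str, int], Mapping[str, bool]]:
    if isinstance(genome, GenomeAssembly):
        return genome.lengths, genome.is_chromosome
    lengths, is_chromosome = genome
    return lengths, is_chromosome


def coverage_report(
    panel: PanelManifest,
    genome: Union[GenomeAssembly, tuple[Mapping[str, int], Mapping[str, bool]]],
    annotation: Optional[GeneAnnotation] = None,
    window: int = 1_000_000,
) -> CoverageReport:
    """Genome coverage of the designed panel.

    Per chromosome: marker count, length (kb), average gap
    (length/count, kb) and markers per Mb (count/(length/1e6)) — the
    usual density table arithmetic. Chromosomes are partitioned into
    consecutive ``window``-bp segments anchored at bp 1 (final segment
    truncated) and empty segments listed. Unplaced contigs are
    summarized by the fraction carrying at least one marker and the
    fraction of contig sequence those represent. Genes count as
    represented when at least one marker lies within their inclusive
    interval.

    ``genome`` may be a full :class:`GenomeAssembly` or a plain
    ``(lengths, is_chromosome)`` mapping pair — only sequence lengths
    enter the arithmetic.
    """
    lengths, is_chromosome = _normalize_genome(genome)
    table = panel.table
    unknown = set(table["seq_name"]) - set(lengths)
    if unknown:
        raise InvalidInputError(f"markers on unknown sequences: {sorted(unknown)[:3]}")

    chrom_rows = {}
    empty_windows: list[tuple[str, int, int]] = []
    n_windows = 0
    n_on_chrom = 0
    for name in sorted(n for n, flag in is_chromosome.items() if flag):
        length = lengths[name]
        positions = np.sort(table.loc[table["seq_name"] == name, "pos"].to_numpy())
        count = len(positions)
        n_on_chrom += count
        length_kb = length / 1000.0
        chrom_rows[name] = {
            "n_markers": count,
            "length_kb": round1(length_kb),
            "avg_gap_kb": round1(length_kb / count) if count else float("nan"),
            "markers_per_mb": round1(count / (length / 1e6)),
        }
        k = 0
        while k * window < length:
            start = k * window + 1
            end = min((k + 1) * window, length)
            n_windows += 1
            lo = np.searchsorted(positions, start, side="left")
            hi = np.searchsorted(positions, end, side="right")
            if hi == lo:
                empty_windows.append((name, start, end))
            k += 1

    contig_names = [n for n, flag in is_chromosome.items() if not flag]
    contigs_with = {
        n for n in set(table["seq_name"]) if n in set(contig_names)
    }
    n_on_contigs = int(table["seq_name"].isin(contig_names).sum())
    total_contig_len = sum(lengths[n] for n in contig_names)
    represented_len = sum(lengths[n] for n in contigs_with)
    contig_fraction = (
        round1(100.0 * len(contigs_with) / len(contig_names))
        if contig_names
        else float("nan")
    )
    contig_seq_fraction = (
        round1(100.0 * represented_len / total_contig_len)
        if total_contig_len
        else float("nan")
    )

    n_genes = n_genes_with = 0
    gene_fraction = float("nan")
    if annotation is not None:
        n_genes = len(annotation)
        by_seq: dict[str, np.ndarray] = {
            n: np.sort(table.loc[table["seq_name"] == n, "pos"].to_numpy())
            for n in set(table["seq_name"])
        }
        for gene in annotation:
            positions = by_seq.get(gene.seq_name)
            if positions is None:
                continue
            lo = np.searchsorted(positions, gene.start, side="left")
            hi = np.searchsorted(positions, gene.end, side="right")
            if hi > lo:
                n_genes_with += 1
        gene_fraction = (
            round1(100.0 * n_genes_with / n_genes) if n_genes else float("nan")
        )

    return CoverageReport(
        per_chromosome=pd.DataFrame.from_dict(chrom_rows, orient="index"),
        empty_windows=empty_windows,
        n_windows=n_windows,
        window_size=window,
        n_contigs=len(contig_names),
        n_contigs_with_marker=len(contigs_with),
        contig_fraction=contig_fraction,
        contig_sequence_fraction=contig_seq_fraction,
        n_genes=n_genes,
        n_genes_with_marker=n_genes_with,
        gene_fraction=gene_fraction,
        n_on_chromosomes=n_on_chrom,
        n_on_contigs=n_on_contigs,
    )


def predict_sex(
    callset: GenotypeCallSet,
    sdy_marker_ids: Sequence[str],
    min_called: int = 1,
) -> pd.DataFrame:
    """Predict genotypic sex from male-limited sdY markers: a sample is
    called male when at least ``min_called`` sdY markers yield a
    genotype. Returns a per-sample frame with predicted and phenotypic
    sex and a concordance flag (NaN when phenotypic sex is unknown)."""
    missing_ids = set(sdy_marker_ids) - set(callset.markers)
    if not sdy_marker_ids or missing_ids:
        raise InvalidInputError(
            f"sdY markers absent from callset: {sorted(missing_ids) or 'none supplied'}"
        )
    sdy_calls = callset.calls.loc[list(sdy_marker_ids)]
    n_called = (sdy_calls != MISSING).sum(axis=0)
    predicted = np.where(n_called >= min_called, "M", "F")
    phenotypic = callset.samples["sex"].reindex(sdy_calls.columns)
    concordant = [
        (p == t) if t in ("M", "F") else np.nan
        for p, t in zip(predicted, phenotypic)
    ]
    return pd.DataFrame(
        {
            "n_sdy_called": n_called,
            "predicted_sex": predicted,
            "phenotypic_sex": phenotypic,
            "concordant": concordant,
        }
    )


def sex_concordance(sex_table: pd.DataFrame) -> float:
    """Fraction of known-sex samples whose predicted sex matches, as a
    percentage (1 decimal)."""
    known = sex_table["concordant"].dropna()
    if known.empty:
        return float("nan")
    return round1(100.0 * float(known.mean()))
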