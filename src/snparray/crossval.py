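"""Cross-platform SNP validation and the high-priority tier.

A candidate is *cross validated* when two independently generated call
sets place a variant at the same genomic position with the same
unordered allele pair. GBS candidates additionally qualify for the
high-priority tier via any of three evidence criteria: (a) detected in
two populations, (b) MAF > 0.05 in at least one population (strict, by
design — the discovery-stage population filter uses >= 0.05), or
(c) segregating in two or more families.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Set

from .model import CandidateSNP, CrossValidationResult, FilterReport, PASS
from .qc import is_strand_ambiguous


def _by_position(
    candidates: Sequence[CandidateSNP],
) -> tuple[dict[tuple[str, int], CandidateSNP], int]:
    """Index candidates by placement; positions claimed with more than one
    distinct allele pair within a set are excluded (multi-allelic
    collision) and counted."""
    index: dict[tuple[str, int], CandidateSNP] = {}
    collided: set[tuple[str, int]] = set()
    for c in candidates:
        key = (c.seq_name, c.pos)
        if key in collided:
            continue
        existing = index.get(key)
        if existing is None:
            index[key] = c
        elif existing.alleles != c.alleles:
            collided.add(key)
            del index[key]
        # identical duplicate: keep first
    return index, len(collided)


def cross_validate(
    set_a: Sequence[CandidateSNP], set_b: Sequence[CandidateSNP]
) -> CrossValidationResult:
    """Match candidates across two platforms by identical (sequence,
    position) and identical unordered allele pair. Symmetric in its
    arguments up to pair ordering; the validated union keeps set_a's
    record as representative."""
    index_a, skip_a = _by_position(set_a)
    index_b, skip_b = _by_position(set_b)
    pairs: list[tuple[str, str]] = []
    validated: list[CandidateSNP] = []
    evidence: dict[str, set[str]] = {}
    for key in sorted(set(index_a) & set(index_b)):
        a, b = index_a[key], index_b[key]
        if a.alleles == b.alleles:
            pairs.append((a.id, b.id))
            validated.append(a)
            evidence[a.id] = {a.platform, b.platform}
    platform_pair = (
        set_a[0].platform if set_a else "?",
        set_b[0].platform if set_b else "?",
    )
    return CrossValidationResult(
        pairs=pairs,
        platform_pair=platform_pair,
        validated=validated,
        evidence=evidence,
        skipped_multiallelic=skip_a + skip_b,
    )


def gbs_priority_select(
    population_maf_reports: Mapping[str, FilterReport],
    population_presence: Mapping[str, Set[str]],
    family_segregating: Mapping[str, Set[str]],
    maf_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Select GBS candidates meeting any of the three evidence criteria.

    ``population_maf_reports`` come from :func:`snparray.qc.filter_population_maf`
    (their ``maf`` column feeds criterion b); ``population_presence``
    maps population -> marker ids present in its raw call set (criterion
    a); ``family_segregating`` maps family -> markers segregating there,
    i.e. heterozygous in at least one parent and passing family QC
    (criterion c). Returns marker id -> list of criteria met.
    """
    selected: dict[str, list[str]] = {}

    presence_count: dict[str, int] = {}
    for markers in population_presence.values():
        for m in markers:
            presence_count[m] = presence_count.get(m, 0) + 1
    for m, n in presence_count.items():
        if n >= 2:
            selected.setdefault(m, []).append("a")

    for report in population_maf_reports.values():
        table = report.table
        if "maf" not in table.columns:
            continue
        hits = table.index[table["maf"] > maf_threshold]
        for m in hits:
            crits = selected.setdefault(m, [])
            if "b" not in crits:
                crits.append("b")

    family_count: dict[str, int] = {}
    for markers in family_segregating.values():
        for m in markers:
            family_count[m] = family_count.get(m, 0) + 1
    for m, n in family_count.items():
        if n >= 2:
            selected.setdefault(m, []).append("c")

    return {m: sorted(crits) for m, crits in selected.items()}


def segregating_markers(parents: Mapping[str, tuple[str, str]],
                        qc_report: Optional[FilterReport] = None) -> set[str]:
    """Markers heterozygous in at least one parent (and, when a family QC
    report is supplied, passing it)."""
    segregating = {m for m, (p1, p2) in parents.items() if "ab" in (p1, p2)}
    if qc_report is not None:
        segregating &= qc_report.passed
    return segregating


def build_high_priority_tier(
    cross_platform: Sequence[CrossValidationResult],
    gbs_selected: Mapping[str, CandidateSNP],
    family_cross_validated: Mapping[str, CandidateSNP] = {},
    ambiguity_exempt_sources: Iterable[str] = (),
) -> tuple[list[CandidateSNP], dict]:
    """Union the cross-platform-validated, GBS-selected and
    family-cross-validated candidates into the tier-1 list.

    Duplicate placements are counted once (cross-platform evidence is
    recorded first); strand-ambiguous (A/T, C/G) candidates are removed
    unless their platform is exempt. Returns the tier-1 list and an audit
    dict with the union arithmetic and the count removed as ambiguous.
    """
    exempt = set(ambiguity_exempt_sources)
    union: dict[tuple[str, int], CandidateSNP] = {}
    overlap = 0
    for result in cross_platform:
        for c in result.validated:
            union.setdefault((c.seq_name, c.pos), c)
    n_cross = len(union)
    for source in (family_cross_validated, gbs_selected):
        for c in source.values():
            key = (c.seq_name, c.pos)
            if key in union:
                overlap += 1
            else:
                union[key] = c
    kept: list[CandidateSNP] = []
    n_ambiguous_removed = 0
    for c in union.values():
        if is_strand_ambiguous(c.ref, c.alt) and c.platform not in exempt:
            n_ambiguous_removed += 1
        else:
            kept.append(c)
    kept.sort(key=lambda c: (c.seq_name, c.pos))
    audit = {
        "n_cross_platform": n_cross,
        "n_candidates_in_union": len(union),
        "n_overlap_counted_once": overlap,
        "n_ambiguous_removed": n_ambiguous_removed,
        "n_tier1": len(kept),
    }
    return kept, audit
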