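"""Assembly of the final array manifest.

Candidates surviving QC are stratified by allele frequency (rare
[0.05, 0.15), common [0.15, 0.85]), labeled for transcript membership,
thinned to spacing targets (~900 kb for the rare stratum, ~62 kb for
common intergenic markers), and combined with the mandatory tiers —
cross-validated high-priority markers and sex-gene (sdY) markers — plus
low-priority putative filler until the array budget is reached. Probes
are emitted in bracket notation ``FLANK[REF/ALT]FLANK`` with the variant
at a fixed offset (71-mer, variant at base 36, by default).
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import (
    MANIFEST_COLUMNS,
    TIER_FILLER,
    TIER_HIGH_PRIORITY,
    TIER_HIGHCOV,
    TIER_SDY,
    CandidateSNP,
    GeneAnnotation,
    GenomeAssembly,
    InvalidInputError,
    PanelManifest,
    SelectionConfig,
)

RARE = "rare"
COMMON = "common"
EXCLUDED = "excluded"


def classify_af(af: Optional[float], config: SelectionConfig) -> str:
    """Assign an AF stratum: rare is left-closed/right-open, common is
    closed on both ends; anything else (or an absent AF) is excluded."""
    if af is None:
        return EXCLUDED
    if not 0.0 <= af <= 1.0:
        raise InvalidInputError(f"AF {af} outside [0, 1]")
    rare_lo, rare_hi = config.rare_af_bounds
    common_lo, common_hi = config.common_af_bounds
    if rare_lo <= af < rare_hi:
        return RARE
    if common_lo <= af <= common_hi:
        return COMMON
    return EXCLUDED


def label_in_transcript(
    candidates: Iterable[CandidateSNP], annotation: GeneAnnotation
) -> list[CandidateSNP]:
    """Set ``in_transcript`` (and ``transcript_id``, comma-joined when a
    position falls inside several overlapping genes) by inclusive
    interval lookup against the gene annotation. Mutates and returns the
    candidates."""
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        trees.setdefault(gene.seq_name, IntervalTree()).addi(
            gene.start, gene.end + 1, gene.gene_id
        )
    out = []
    for c in candidates:
        tree = trees.get(c.seq_name)
        hits = sorted(iv.data for iv in tree[c.pos]) if tree else []
        c.in_transcript = bool(hits)
        c.transcript_id = ",".join(hits) if hits else c.transcript_id
        out.append(c)
    return out


def default_ranker(c: CandidateSNP, scores: Mapping[str, float] = {}) -> tuple:
    """Deterministic candidate ordering: higher external conversion score
    first, then AF closest to 0.5, then smaller position, then id."""
    score = scores.get(c.id, 0.0)
    af_dist = abs((c.af if c.af is not None else 0.0) - 0.5)
    return (-score, af_dist, c.pos, c.id)


def select_spaced(
    candidates: Sequence[CandidateSNP],
    target_interval: int,
    ranker: Optional[Callable[[CandidateSNP], tuple]] = None,
    mode: str = "window",
) -> list[CandidateSNP]:
    """Thin a position-sorted candidate list on one sequence to roughly
    one marker per ``target_interval`` bp.

    ``window`` mode partitions the sequence into consecutive
    ``target_interval`` windows anchored at bp 1 and keeps the best
    candidate (under ``ranker``) per nonempty window, so consecutive
    picks are < 2x the target apart whenever intervening windows hold
    candidates. ``greedy`` mode keeps the next candidate at least the
    target beyond the last pick."""
    if target_interval <= 0:
        raise InvalidInputError("target_interval must be positive")
    positions = [c.pos for c in candidates]
    if positions != sorted(positions):
        raise InvalidInputError("candidates must be sorted by position")
    if not candidates:
        return []
    rank = ranker or default_ranker
    if mode == "greedy":
        picks = [candidates[0]]
        for c in candidates[1:]:
            if c.pos - picks[-1].pos >= target_interval:
                picks.append(c)
        return picks
    if mode != "window":
        raise InvalidInputError(f"unknown spacing mode {mode!r}")
    windows: dict[int, CandidateSNP] = {}
    for c in candidates:
        w = (c.pos - 1) // target_interval
        best = windows.get(w)
        if best is None or rank(c) < rank(best):
            windows[w] = c
    return [windows[w] for w in sorted(windows)]


def select_spaced_genome(
    candidates: Sequence[CandidateSNP],
    target_interval: int,
    ranker: Optional[Callable[[CandidateSNP], tuple]] = None,
    mode: str = "window",
) -> list[CandidateSNP]:
    """Apply :func:`select_spaced` per sequence over a mixed candidate pool."""
    by_seq: dict[str, list[CandidateSNP]] = {}
    for c in candidates:
        by_seq.setdefault(c.seq_name, []).append(c)
    picks: list[CandidateSNP] = []
    for seq_name in sorted(by_seq):
        chunk = sorted(by_seq[seq_name], key=lambda c: c.pos)
        picks.extend(select_spaced(chunk, target_interval, ranker, mode))
    return picks


def make_probe(
    c: CandidateSNP,
    genome: GenomeAssembly,
    length: int = 71,
    snp_offset: int = 36,
) -> str:
    """Build the submission probe: forward-strand flanks around the
    variant with both alleles in brackets, variant base at 1-based
    ``snp_offset`` of the ``length``-mer."""
    left_need = snp_offset - 1
    right_need = length - snp_offset
    left_avail = c.pos - 1
    right_avail = len(genome.sequences[c.seq_name]) - c.pos
    if left_avail < left_need:
        raise InvalidInputError(
            f"{c.id}: left flank {left_avail} bp < required {left_need}"
        )
    if right_avail < right_need:
        raise InvalidInputError(
            f"{c.id}: right flank {right_avail} bp < required {right_need}"
        )
    left = genome.subseq(c.seq_name, c.pos - left_need, c.pos - 1)
    right = genome.subseq(c.seq_name, c.pos + 1, c.pos + right_need)
    return f"{left}[{c.ref}/{c.alt}]{right}"


def probe_plain(probe: str) -> str:
    """The plain-sequence form of a bracket probe (reference allele in)."""
    start = probe.index("[")
    end = probe.index("]")
    ref = probe[start + 1 : end].split("/")[0]
    return probe[:start] + ref + probe[end + 1 :]


def include_sdy_markers(
    sdy_candidates: Sequence[CandidateSNP], min_flank: int = 35
) -> tuple[list[CandidateSNP], dict]:
    """Pass all sex-gene markers through unconditionally (they bypass AF
    and spacing rules); markers with short flanks are still included but
    flagged in the audit."""
    from .qc import check_flank_length

    audit = {
        "n_sdy": len(sdy_candidates),
        "flank_flagged": [
            c.id for c in sdy_candidates if not check_flank_length(c, min_flank)
        ],
    }
    return list(sdy_candidates), audit


NOT_RECOMMENDED = "not_recommended"


def assemble_panel(
    tier1: Sequence[CandidateSNP],
    sdy: Sequence[CandidateSNP],
    highcov_rare: Sequence[CandidateSNP],
    highcov_common_intergenic: Sequence[CandidateSNP],
    filler_pool: Sequence[CandidateSNP],
    genome: GenomeAssembly,
    config: SelectionConfig,
    conversion_scores: Optional[Mapping[str, tuple[float, str]]] = None,
) -> PanelManifest:
    """Assemble the manifest in deterministic fill order.

    Tiers: (1) the high-priority cross-validated set, entire; (2) sdY
    markers, entire; (3) spacing-thinned high-coverage pools — rare at
    the rare target, common intergenic at the common target; (4) filler
    from the low-priority putative pool, ranked, until the budget is
    reached or pools are exhausted. When ``conversion_scores`` (id ->
    (score, label)) are supplied, candidates labeled ``not_recommended``
    are dropped before filling and a top-up pass from the remaining
    common intergenic pool replaces them. Probes are built for every
    selected marker; markers without room for a full probe are dropped
    with a reason. The audit preserves |input| = |selected| + |dropped|.
    """
    scores = conversion_scores or {}
    mandatory = len(tier1) + len(sdy)
    if config.budget < mandatory:
        raise InvalidInputError(
            f"budget {config.budget} below mandatory tiers ({mandatory})"
        )

    score_values = {mid: s for mid, (s, _label) in scores.items()}
    ranker = lambda c: default_ranker(c, score_values)  # noqa: E731

    all_inputs: list[CandidateSNP] = [
        *tier1, *sdy, *highcov_rare, *highcov_common_intergenic, *filler_pool
    ]
    drop_reasons: dict[str, str] = {}

    def screened(pool: Sequence[CandidateSNP]) -> list[CandidateSNP]:
        kept = []
        for c in pool:
            label = scores.get(c.id, (0.0, ""))[1]
            if label == NOT_RECOMMENDED:
                drop_reasons[c.id] = "external score: not recommended"
            else:
                kept.append(c)
        return kept

    tier3_rare = select_spaced_genome(
        screened(highcov_rare), config.rare_spacing, ranker, config.spacing_mode
    )
    common_screened = screened(highcov_common_intergenic)
    tier3_common = select_spaced_genome(
        common_screened, config.common_spacing, ranker, config.spacing_mode
    )

    rows: list[dict] = []
    chosen: set[str] = set()

    def admit(c: CandidateSNP, tier: int, reason: str) -> bool:
        if c.id in chosen:
            drop_reasons.setdefault(c.id, "duplicate of already-selected marker")
            return False
        if len(rows) >= config.budget:
            drop_reasons[c.id] = "budget exhausted"
            return False
        try:
            probe = make_probe(c, genome, config.probe_length, config.snp_offset)
        except InvalidInputError as exc:
            drop_reasons[c.id] = f"probe: {exc}"
            return False
        score, _ = scores.get(c.id, (None, ""))
        rows.append(
            {
                "marker_id": c.id,
                "seq_name": c.seq_name,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "tier": tier,
                "reason": reason,
                "in_transcript": c.in_transcript,
                "probe": probe,
                "platform": c.platform,
                "score": score,
            }
        )
        chosen.add(c.id)
        drop_reasons.pop(c.id, None)
        return True

    for c in screened(tier1):
        admit(c, TIER_HIGH_PRIORITY, "high-priority (cross validated / GBS criteria)")
    for c in sdy:  # sdY bypasses the external-score screen
        admit(c, TIER_SDY, "sdY sex marker")
    for c in tier3_rare:
        admit(c, TIER_HIGHCOV, f"rare stratum, ~{config.rare_spacing} bp spacing")
    for c in tier3_common:
        admit(c, TIER_HIGHCOV, f"common intergenic, ~{config.common_spacing} bp spacing")
    for c in sorted(screened(filler_pool), key=ranker):
        if len(rows) >= config.budget:
            drop_reasons[c.id] = "budget exhausted"
            continue
        admit(c, TIER_FILLER, "low-priority putative filler")

    # top-up: if screening or probe failures left room on the array, draw
    # further common intergenic candidates (beyond the spacing picks)
    if len(rows) < config.budget:
        leftover = [c for c in common_screened if c.id not in chosen]
        for c in sorted(leftover, key=ranker):
            if len(rows) >= config.budget:
                break
            admit(c, TIER_HIGHCOV, "common intergenic top-up")

    for c in all_inputs:
        if c.id not in chosen:
            drop_reasons.setdefault(c.id, "spacing: thinned to interval target")
    dropped = sorted(drop_reasons.items())

    table = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    audit = {
        "n_input": len({c.id for c in all_inputs}),
        "n_selected": len(table),
        "n_dropped": len(dropped),
        "dropped": dropped,
        "n_rare_after_spacing": len(tier3_rare),
        "n_common_after_spacing": len(tier3_common),
        "budget": config.budget,
        "shortfall": max(0, config.budget - len(table)),
    }
    return PanelManifest(table=table, audit=audit)


def conversion_rate(n_included: int, n_submitted: int) -> float:
    """Percentage of submitted candidates that made the final design,
    rounded to one decimal (round-half-even)."""
    from .evaluate import round1

    if n_submitted == 0:
        return float("nan")
    return round1(100.0 * n_included / n_submitted)
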