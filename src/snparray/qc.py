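"""Per-candidate and per-marker QC rules applied before array design.

Family-derived markers face three rules — progeny missingness, Mendelian
transmission errors, and segregation distortion — with the convention
that a marker carried by several families is removed only when it fails
in *all* of them. Population-derived markers face a minor-allele-frequency
floor. High-coverage sequencing records face two staged quality filters
(initial calling vs. design). All printed inequality boundaries are
applied exactly as stated (each has a dedicated unit test); records with
missing required fields get a distinct ``not_testable`` status rather
than silently passing.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    FAIL,
    MISSING,
    NOT_TESTABLE,
    PASS,
    CandidateSNP,
    FamilyGenotypes,
    FilterReport,
    GenomeAssembly,
    InvalidInputError,
    PopulationGenotypes,
    reverse_complement,
)
from .simulate import _ALLELES


def _report(rule: str, rows: dict[str, dict]) -> FilterReport:
    table = pd.DataFrame.from_dict(rows, orient="index")
    if "reason" not in table.columns:
        table["reason"] = ""
    return FilterReport(rule=rule, table=table)


def filter_missingness(fam: FamilyGenotypes, max_missing: float = 0.5) -> FilterReport:
    """Fail markers whose missing fraction among progeny exceeds
    ``max_missing`` (strictly; exactly at the threshold passes)."""
    if not 0.0 <= max_missing <= 1.0:
        raise InvalidInputError("max_missing outside [0, 1]")
    if fam.n_progeny < 1:
        raise InvalidInputError("family has no progeny")
    frac = (fam.progeny == MISSING).mean(axis=1)
    rows = {
        m: {
            "status": FAIL if f > max_missing else PASS,
            "missing_fraction": float(f),
            "reason": f"missing fraction {f:.3f} > {max_missing}" if f > max_missing else "",
        }
        for m, f in frac.items()
    }
    return _report("missingness", rows)


def _consistent_genotypes(p1: str, p2: str) -> set[str]:
    return {
        "".join(sorted(a1 + a2)) for a1 in _ALLELES[p1] for a2 in _ALLELES[p2]
    }


def detect_mendelian_errors(
    fam: FamilyGenotypes, max_error_cells: int = 0
) -> FilterReport:
    """Flag progeny genotypes impossible under Mendelian transmission from
    the recorded parents (one allele from each parent); a marker fails
    when it carries more than ``max_error_cells`` flagged cells. Missing
    genotypes never count as errors. The report carries an
    ``error_cells`` column listing flagged (progeny id) entries."""
    rows = {}
    for m in fam.markers:
        parents = fam.parents.get(m)
        if parents is None:
            rows[m] = {"status": NOT_TESTABLE, "reason": "no parent genotypes",
                       "n_errors": 0, "error_cells": ""}
            continue
        p1, p2 = parents
        if p1 not in _ALLELES or p2 not in _ALLELES:
            raise InvalidInputError(
                f"marker {m}: unknown parent genotype {p1!r}/{p2!r}"
            )
        allowed = _consistent_genotypes(p1, p2)
        row = fam.progeny.loc[m]
        bad = [pid for pid, g in row.items() if g != MISSING and g not in allowed]
        status = FAIL if len(bad) > max_error_cells else PASS
        rows[m] = {
            "status": status,
            "n_errors": len(bad),
            "error_cells": ",".join(bad),
            "reason": f"{len(bad)} Mendelian-inconsistent progeny" if bad else "",
        }
    return _report("mendelian", rows)


# cross type -> (expected classes, expected proportions)
_SEGREGATION_EXPECTATIONS: dict[tuple[str, str], tuple[list[str], list[float]]] = {
    ("aa", "ab"): (["aa", "ab"], [0.5, 0.5]),
    ("ab", "aa"): (["aa", "ab"], [0.5, 0.5]),
    ("bb", "ab"): (["ab", "bb"], [0.5, 0.5]),
    ("ab", "bb"): (["ab", "bb"], [0.5, 0.5]),
    ("ab", "ab"): (["aa", "ab", "bb"], [0.25, 0.5, 0.25]),
}


def test_segregation_distortion(
    fam: FamilyGenotypes, alpha: float = 0.01, bonferroni: bool = False
) -> FilterReport:
    """Chi-square goodness-of-fit of progeny counts against Mendelian
    expectations (1:1 for backcross-type markers, 1:2:1 for ab x ab).

    Uninformative crosses (aa x aa, bb x bb, aa x bb) are reported
    ``not_testable``. Genotypes impossible under the cross are excluded
    from the table (they are the Mendelian-error filter's concern). A
    marker fails iff p < alpha (optionally Bonferroni-corrected over the
    testable markers)."""
    testable = [
        m for m in fam.markers if tuple(fam.parents.get(m, ("", ""))) in _SEGREGATION_EXPECTATIONS
    ]
    threshold = alpha / len(testable) if (bonferroni and testable) else alpha
    rows = {}
    for m in fam.markers:
        parents = tuple(fam.parents.get(m, ("", "")))
        expectation = _SEGREGATION_EXPECTATIONS.get(parents)
        if expectation is None:
            rows[m] = {"status": NOT_TESTABLE, "reason": "uninformative cross",
                       "chi2": np.nan, "pvalue": np.nan}
            continue
        classes, props = expectation
        counts = Counter(g for g in fam.progeny.loc[m] if g in classes)
        observed = np.array([counts.get(c, 0) for c in classes], dtype=float)
        n = observed.sum()
        if n == 0:
            rows[m] = {"status": NOT_TESTABLE, "reason": "no informative progeny",
                       "chi2": np.nan, "pvalue": np.nan}
            continue
        chi2, pvalue = stats.chisquare(observed, f_exp=n * np.array(props))
        rows[m] = {
            "status": FAIL if pvalue < threshold else PASS,
            "chi2": float(chi2),
            "pvalue": float(pvalue),
            "reason": f"distorted (p={pvalue:.2e})" if pvalue < threshold else "",
        }
    return _report("segregation", rows)


def combine_family_reports(reports: Mapping[str, FilterReport]) -> FilterReport:
    """Apply the all-families removal rule: a marker fails overall only if
    it fails in every family where it was testable; markers passing in at
    least one family are retained."""
    verdict: dict[str, dict] = {}
    for fam_id, report in reports.items():
        for m in report.table.index:
            status = report.table.loc[m, "status"]
            entry = verdict.setdefault(m, {"n_fail": 0, "n_pass": 0, "n_nt": 0})
            key = {PASS: "n_pass", FAIL: "n_fail", NOT_TESTABLE: "n_nt"}[status]
            entry[key] += 1
    rows = {}
    for m, entry in verdict.items():
        testable = entry["n_pass"] + entry["n_fail"]
        if testable == 0:
            status = NOT_TESTABLE
        elif entry["n_pass"] > 0:
            status = PASS
        else:
            status = FAIL
        rows[m] = {
            "status": status,
            "reason": "failed in all families" if status == FAIL else "",
            **entry,
        }
    return _report("all_families", rows)


def family_qc(
    families: Sequence[FamilyGenotypes],
    max_missing: float = 0.5,
    alpha: float = 0.01,
) -> FilterReport:
    """Compose the three family rules per family (a marker fails within a
    family if it trips any rule), then apply the all-families rule."""
    per_family: dict[str, FilterReport] = {}
    for fam in families:
        miss = filter_missingness(fam, max_missing)
        mend = detect_mendelian_errors(fam)
        seg = test_segregation_distortion(fam, alpha)
        rows = {}
        for m in fam.markers:
            statuses = [r.table.loc[m, "status"] for r in (miss, mend, seg)]
            if FAIL in statuses:
                status, reason = FAIL, ";".join(
                    r.table.loc[m, "reason"]
                    for r in (miss, mend, seg)
                    if r.table.loc[m, "status"] == FAIL
                )
            elif all(s == NOT_TESTABLE for s in statuses):
                status, reason = NOT_TESTABLE, "no testable rule"
            else:
                status, reason = PASS, ""
            rows[m] = {"status": status, "reason": reason}
        per_family[fam.family_id] = _report("family_qc", rows)
    return combine_family_reports(per_family)


def compute_maf(genotypes: pd.Series) -> float:
    """Minor allele frequency by allele counting over non-missing calls."""
    counts = Counter(g for g in genotypes if g != MISSING)
    n_a = 2 * counts.get("aa", 0) + counts.get("ab", 0)
    n_b = 2 * counts.get("bb", 0) + counts.get("ab", 0)
    total = n_a + n_b
    if total == 0:
        return float("nan")
    return min(n_a, n_b) / total


def filter_population_maf(
    pop: PopulationGenotypes, min_maf: float = 0.05
) -> FilterReport:
    """Pass markers with MAF >= ``min_maf`` (inclusive); all-missing
    markers are ``not_testable``."""
    rows = {}
    for m in pop.markers:
        maf = compute_maf(pop.genotypes.loc[m])
        if np.isnan(maf):
            rows[m] = {"status": NOT_TESTABLE, "maf": maf, "reason": "all genotypes missing"}
        else:
            ok = maf >= min_maf
            rows[m] = {
                "status": PASS if ok else FAIL,
                "maf": maf,
                "reason": "" if ok else f"MAF {maf:.3f} < {min_maf}",
            }
    return _report("population_maf", rows)


# ---------------------------------------------------------------------------
# High-coverage record filters

# stage -> field -> (low, high), inclusive on both ends; None = unbounded
HIGHCOV_STAGES: dict[str, dict[str, tuple[Optional[float], Optional[float]]]] = {
    "initial": {"qual": (20, None), "mq": (30, None), "gq": (20, None), "dp": (1, 100)},
    "design": {"dp": (5, 45), "qual": (20, None), "gq": (20, None), "mq": (30, None)},
}


def filter_highcov_record(c: CandidateSNP, stage: str) -> tuple[str, str]:
    """Apply one stage of the high-coverage quality filters to a record.

    Returns ``(status, reason)`` where status is pass/fail/not_testable;
    every comparison is inclusive."""
    if stage not in HIGHCOV_STAGES:
        raise InvalidInputError(f"unknown stage {stage!r}")
    for field_name, (lo, hi) in HIGHCOV_STAGES[stage].items():
        value = getattr(c, field_name)
        if value is None:
            return NOT_TESTABLE, f"missing {field_name.upper()}"
        if lo is not None and value < lo:
            return FAIL, f"{field_name.upper()} {value} < {lo}"
        if hi is not None and value > hi:
            return FAIL, f"{field_name.upper()} {value} > {hi}"
    return PASS, ""


def filter_highcov(candidates: Iterable[CandidateSNP], stage: str) -> FilterReport:
    rows = {}
    for c in candidates:
        status, reason = filter_highcov_record(c, stage)
        rows[c.id] = {"status": status, "reason": reason}
    return _report(f"highcov_{stage}", rows)


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    """A/T and C/G polymorphisms read identically on both strands and
    need twice the assays on a hybridization array."""
    for allele in (ref, alt):
        if allele not in "ACGT" or len(allele) != 1:
            raise InvalidInputError(f"non-ACGT allele {allele!r}")
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def check_flank_length(c: CandidateSNP, min_flank: int = 35) -> bool:
    """True iff both flanks carry at least ``min_flank`` bp."""
    return len(c.left_flank) >= min_flank and len(c.right_flank) >= min_flank


def count_genome_placements(query: str, genome: GenomeAssembly) -> int:
    """Count exact placements of ``query`` in the genome on both strands
    (overlapping occurrences included). Callers treat count == 1 as the
    single-placement requirement; note a palindromic query counts each
    site once per strand."""
    if len(query) < 20:
        raise InvalidInputError("query shorter than 20 bp")
    total = 0
    for probe in (query, reverse_complement(query)):
        for seq in genome.sequences.values():
            start = 0
            while True:
                hit = seq.find(probe, start)
                if hit == -1:
                    break
                total += 1
                start = hit + 1
    return total


def deduplicate_candidates(
    sets: Sequence[Sequence[CandidateSNP]],
) -> tuple[list[CandidateSNP], dict[str, str]]:
    """Collapse candidates with identical flank+allele sequence and
    allele pair across call sets; the earliest source order wins.
    Returns the unique list and a map duplicate id -> retained id."""
    seen: dict[tuple, CandidateSNP] = {}
    duplicates: dict[str, str] = {}
    for candidate_set in sets:
        for c in candidate_set:
            key = (c.tag_sequence, c.alleles)
            if key in seen:
                duplicates[c.id] = seen[key].id
            else:
                seen[key] = c
    return list(seen.values()), duplicates


def exclude_transcript_ambiguity(candidates: Sequence[CandidateSNP]) -> FilterReport:
    """Exclude every candidate on a transcript claimed by candidates from
    two or more distinct source contigs (ambiguous placement)."""
    contigs_per_transcript: dict[str, set[str]] = {}
    for c in candidates:
        if c.transcript_id and c.source_contig:
            contigs_per_transcript.setdefault(c.transcript_id, set()).add(
                c.source_contig
            )
    ambiguous = {t for t, contigs in contigs_per_transcript.items() if len(contigs) >= 2}
    rows = {}
    for c in candidates:
        if c.transcript_id in ambiguous:
            rows[c.id] = {
                "status": FAIL,
                "reason": f"transcript {c.transcript_id} hit by multiple contigs",
            }
        else:
            rows[c.id] = {"status": PASS, "reason": ""}
    return _report("transcript_ambiguity", rows)
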