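"""QC rule boundaries (each printed inequality exactly as stated),
Mendelian transmission enumeration, the segregation chi-square worked
example and its type-I calibration, MAF arithmetic against an
independent oracle, and exact-placement counting against a brute-force
scan."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snparray.model import (
    FAIL,
    NOT_TESTABLE,
    PASS,
    FamilyGenotypes,
    InvalidInputError,
    PopulationGenotypes,
    reverse_complement,
)
from snparray.qc import (
    check_flank_length,
    combine_family_reports,
    compute_maf,
    count_genome_placements,
    deduplicate_candidates,
    detect_mendelian_errors,
    exclude_transcript_ambiguity,
    filter_highcov_record,
    filter_missingness,
    filter_population_maf,
    is_strand_ambiguous,
)
from snparray.qc import test_segregation_distortion as segregation_test
from snparray.simulate import generate_genome, simulate_family

from conftest import make_candidate


def family(parents, progeny_rows, family_id="f1"):
    markers = list(parents)
    n = len(next(iter(progeny_rows.values())))
    frame = pd.DataFrame(
        progeny_rows, index=[f"p{j}" for j in range(n)]
    ).T.reindex(markers)
    frame.columns = [f"p{j}" for j in range(n)]
    return FamilyGenotypes(family_id=family_id, parents=parents, progeny=frame)


def family_from_lists(parents, rows, family_id="f1"):
    markers = list(parents)
    frame = pd.DataFrame(
        {m: rows[m] for m in markers}, dtype=str
    ).T
    frame.columns = [f"p{j}" for j in range(frame.shape[1])]
    return FamilyGenotypes(family_id=family_id, parents=parents, progeny=frame)


class TestMissingness:
    def test_six_of_ten_missing_fails(self):
        fam = family_from_lists({"m": ("aa", "ab")}, {"m": ["--"] * 6 + ["aa"] * 4})
        assert filter_missingness(fam).failed == {"m"}

    def test_exactly_half_missing_passes(self):
        fam = family_from_lists({"m": ("aa", "ab")}, {"m": ["--"] * 5 + ["aa"] * 5})
        assert filter_missingness(fam).passed == {"m"}

    def test_all_families_rule_retains_marker(self):
        f1 = family_from_lists({"m": ("aa", "ab")}, {"m": ["--"] * 6 + ["aa"] * 4}, "f1")
        f2 = family_from_lists({"m": ("aa", "ab")}, {"m": ["aa"] * 10}, "f2")
        combined = combine_family_reports(
            {"f1": filter_missingness(f1), "f2": filter_missingness(f2)}
        )
        assert combined.passed == {"m"}

    def test_fails_only_when_failing_everywhere(self):
        f1 = family_from_lists({"m": ("aa", "ab")}, {"m": ["--"] * 6 + ["aa"] * 4}, "f1")
        f2 = family_from_lists({"m": ("aa", "ab")}, {"m": ["--"] * 7 + ["ab"] * 3}, "f2")
        combined = combine_family_reports(
            {"f1": filter_missingness(f1), "f2": filter_missingness(f2)}
        )
        assert combined.failed == {"m"}


class TestMendelianErrors:
    def test_bb_under_aa_x_ab_flagged(self):
        fam = family_from_lists({"m": ("aa", "ab")}, {"m": ["aa", "ab", "bb"]})
        report = detect_mendelian_errors(fam)
        assert report.failed == {"m"}
        assert report.table.loc["m", "n_errors"] == 1

    def test_bb_under_ab_x_ab_not_flagged(self):
        fam = family_from_lists({"m": ("ab", "ab")}, {"m": ["aa", "ab", "bb"]})
        assert detect_mendelian_errors(fam).passed == {"m"}

    def test_missing_never_an_error(self):
        fam = family_from_lists({"m": ("aa", "aa")}, {"m": ["--", "--", "aa"]})
        assert detect_mendelian_errors(fam).passed == {"m"}

    def test_full_enumeration_against_transmission_rule(self):
        """Every parent-pair x progeny combination checked against a
        brute-force allele-transmission oracle."""
        alleles = {"aa": "aa", "ab": "ab", "bb": "bb"}
        for p1, p2, child in product(alleles, repeat=3):
            possible = {
                "".join(sorted(a + b)) for a in alleles[p1] for b in alleles[p2]
            }
            fam = family_from_lists({"m": (p1, p2)}, {"m": [child]})
            report = detect_mendelian_errors(fam)
            if child in possible:
                assert report.passed == {"m"}, (p1, p2, child)
            else:
                assert report.failed == {"m"}, (p1, p2, child)

    def test_unknown_parent_code_rejected(self):
        fam = family_from_lists({"m": ("aa", "aa")}, {"m": ["aa"]})
        fam.parents["m"] = ("aa", "zz")
        with pytest.raises(InvalidInputError):
            detect_mendelian_errors(fam)

    def test_sensitivity_and_specificity_on_labeled_family(self):
        """All detectable injected errors flagged; zero clean cells flagged."""
        rng = np.random.default_rng(21)
        cross = {
            f"m{i}": tuple(rng.choice(["aa", "ab", "bb"], size=2)) for i in range(100)
        }
        fam, truth = simulate_family(
            cross, 50, mendelian_error_rate=0.03, missing_rate=0.02, seed=22
        )
        report = detect_mendelian_errors(fam)
        flagged = set()
        for m in fam.markers:
            cells = report.table.loc[m, "error_cells"]
            flagged |= {(m, pid) for pid in cells.split(",") if pid}
        # independent oracle: a cell is detectable iff inconsistent with parents
        detectable = set()
        for m in fam.markers:
            p1, p2 = cross[m]
            possible = {"".join(sorted(a + b)) for a in p1 for b in p2}
            for pid, g in fam.progeny.loc[m].items():
                if g not in ("--",) and g not in possible:
                    detectable.add((m, pid))
        assert flagged == detectable
        assert detectable <= truth.error_cells  # no clean cell is detectable
        assert len(detectable) > 0


class TestSegregation:
    def test_exact_expectation_passes(self):
        rows = {"m": ["aa"] * 25 + ["ab"] * 50 + ["bb"] * 25}
        fam = family_from_lists({"m": ("ab", "ab")}, rows)
        report = segregation_test(fam)
        assert report.table.loc["m", "chi2"] == pytest.approx(0.0)
        assert report.table.loc["m", "pvalue"] == pytest.approx(1.0)
        assert report.passed == {"m"}

    def test_worked_example_40_40_20(self):
        rows = {"m": ["aa"] * 40 + ["ab"] * 40 + ["bb"] * 20}
        fam = family_from_lists({"m": ("ab", "ab")}, rows)
        report = segregation_test(fam, alpha=0.01)
        assert report.table.loc["m", "chi2"] == pytest.approx(12.0)
        assert report.table.loc["m", "pvalue"] == pytest.approx(0.00248, abs=5e-5)
        assert report.failed == {"m"}

    def test_uninformative_crosses_not_testable(self):
        parents = {"m1": ("aa", "aa"), "m2": ("bb", "bb"), "m3": ("aa", "bb")}
        rows = {"m1": ["aa"] * 4, "m2": ["bb"] * 4, "m3": ["ab"] * 4}
        fam = family_from_lists(parents, rows)
        assert segregation_test(fam).not_testable == set(parents)

    def test_backcross_1_to_1(self):
        rows = {"m": ["aa"] * 30 + ["ab"] * 70}
        fam = family_from_lists({"m": ("aa", "ab")}, rows)
        report = segregation_test(fam, alpha=0.01)
        chi2, p = stats.chisquare([30, 70], f_exp=[50, 50])
        assert report.table.loc["m", "chi2"] == pytest.approx(chi2)
        assert report.failed == {"m"}

    def test_type_i_error_within_3_sigma(self):
        cross = {f"m{i}": ("ab", "ab") for i in range(2000)}
        fam, _ = simulate_family(cross, 100, seed=7)
        report = segregation_test(fam, alpha=0.01)
        rate = len(report.failed) / 2000
        sigma = (0.01 * 0.99 / 2000) ** 0.5
        assert abs(rate - 0.01) < 3 * sigma

    def test_power_above_090_at_lambda_30(self):
        """At n=250 progeny and distortion giving class probabilities
        (0.4, 0.4, 0.2), the noncentral chi-square power exceeds 0.9."""
        rng = np.random.default_rng(31)
        rejected = 0
        n_sim = 400
        for _ in range(n_sim):
            counts = rng.multinomial(250, [0.4, 0.4, 0.2])
            _, p = stats.chisquare(counts, f_exp=[62.5, 125.0, 62.5])
            rejected += p < 0.01
        assert rejected / n_sim > 0.9


class TestPopulationMaf:
    def test_allele_counting(self):
        rows = {"m": ["ab"] * 3 + ["aa"] * 7}
        pop = PopulationGenotypes("g", pd.DataFrame(rows, dtype=str).T)
        report = filter_population_maf(pop)
        assert report.table.loc["m", "maf"] == pytest.approx(3 / 20)
        assert report.passed == {"m"}

    def test_boundary_inclusive(self):
        # MAF exactly 0.05: 1 het among 10 samples
        rows = {"m": ["ab"] + ["aa"] * 9}
        pop = PopulationGenotypes("g", pd.DataFrame(rows, dtype=str).T)
        report = filter_population_maf(pop, min_maf=0.05)
        assert report.table.loc["m", "maf"] == pytest.approx(0.05)
        assert report.passed == {"m"}

    def test_monomorphic_fails(self):
        rows = {"m": ["aa"] * 10}
        pop = PopulationGenotypes("g", pd.DataFrame(rows, dtype=str).T)
        assert filter_population_maf(pop).failed == {"m"}

    def test_all_missing_not_testable(self):
        rows = {"m": ["--"] * 5}
        pop = PopulationGenotypes("g", pd.DataFrame(rows, dtype=str).T)
        assert filter_population_maf(pop).not_testable == {"m"}

    def test_maf_matches_independent_oracle(self):
        rng = np.random.default_rng(17)
        genotypes = rng.choice(["aa", "ab", "bb", "--"], size=200)
        maf = compute_maf(pd.Series(genotypes))
        # oracle: literal allele tally
        a = b = 0
        for g in genotypes:
            if g == "aa":
                a += 2
            elif g == "ab":
                a += 1
                b += 1
            elif g == "bb":
                b += 2
        assert maf == pytest.approx(min(a, b) / (a + b))


class TestHighcovFilters:
    def test_design_boundaries_inclusive(self):
        c = make_candidate(dp=45, qual=20, gq=20, mq=30)
        assert filter_highcov_record(c, "design") == (PASS, "")

    def test_dp_46_fails_design(self):
        c = make_candidate(dp=46, qual=20, gq=20, mq=30)
        status, reason = filter_highcov_record(c, "design")
        assert status == FAIL and "DP" in reason

    def test_initial_passes_design_fails_on_low_depth(self):
        c = make_candidate(dp=3, qual=25, gq=25, mq=35)
        assert filter_highcov_record(c, "initial")[0] == PASS
        status, reason = filter_highcov_record(c, "design")
        assert status == FAIL and "DP" in reason

    def test_initial_boundaries(self):
        assert filter_highcov_record(
            make_candidate(dp=1, qual=20, gq=20, mq=30), "initial"
        )[0] == PASS
        assert filter_highcov_record(
            make_candidate(dp=101, qual=20, gq=20, mq=30), "initial"
        )[0] == FAIL

    def test_missing_field_not_testable(self):
        c = make_candidate(dp=None, qual=20, gq=20, mq=30)
        status, reason = filter_highcov_record(c, "design")
        assert status == NOT_TESTABLE and "DP" in reason


class TestStrandAmbiguity:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "T", True), ("T", "A", True), ("G", "C", True), ("C", "G", True),
        ("A", "C", False), ("A", "G", False), ("T", "G", False), ("C", "T", False),
    ])
    def test_pairs(self, ref, alt, expected):
        assert is_strand_ambiguous(ref, alt) is expected

    def test_non_acgt_rejected(self):
        with pytest.raises(InvalidInputError):
            is_strand_ambiguous("N", "A")


class TestFlankLength:
    @pytest.mark.parametrize("left,right,expected", [
        (35, 35, True), (34, 80, False), (0, 0, False), (80, 34, False),
    ])
    def test_boundaries(self, left, right, expected):
        c = make_candidate(left_flank="A" * left, right_flank="C" * right)
        assert check_flank_length(c) is expected


def brute_force_placements(query: str, genome) -> int:
    """Independent oracle: vectorized sliding-window character match."""
    total = 0
    for probe in (query, reverse_complement(query)):
        q = np.frombuffer(probe.encode(), dtype=np.uint8)
        for seq in genome.sequences.values():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            n, m = len(arr), len(q)
            if m > n:
                continue
            match = np.ones(n - m + 1, dtype=bool)
            for i in range(m):
                match &= arr[i : n - m + 1 + i] == q[i]
            total += int(match.sum())
    return total


class TestGenomePlacements:
    def test_single_forward_hit(self, toy_genome):
        chrom = toy_genome.chromosomes[0]
        query = toy_genome.subseq(chrom, 1000, 1040)
        count = count_genome_placements(query, toy_genome)
        assert count == brute_force_placements(query, toy_genome)

    def test_planted_duplicate_counted(self):
        from snparray.model import GenomeAssembly
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=2000))
        segment = base[100:140]
        seq = base + segment + base[500:700]
        genome = GenomeAssembly({"chr1": seq}, {"chr1": True})
        assert count_genome_placements(segment, genome) >= 2

    def test_reverse_strand_hit_counts(self):
        from snparray.model import GenomeAssembly
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(list("ACGT"), size=1000))
        query = base[200:240]
        genome = GenomeAssembly(
            {"chr1": base, "chr2": "G" * 100 + reverse_complement(query) + "T" * 100},
            {"chr1": True, "chr2": True},
        )
        assert count_genome_placements(query, genome) == brute_force_placements(
            query, genome
        )
        assert count_genome_placements(query, genome) >= 2

    def test_absent_query_zero(self, toy_genome):
        assert count_genome_placements("A" * 40, toy_genome) in (
            brute_force_placements("A" * 40, toy_genome),
        )

    def test_short_query_rejected(self, toy_genome):
        with pytest.raises(InvalidInputError):
            count_genome_placements("ACGT", toy_genome)

    def test_agrees_with_brute_force_on_random_queries(self):
        """Implementation vs independent O(n*m) scan on a 100 kb genome."""
        genome = generate_genome(2, 50_000, 0, seed=41)
        rng = np.random.default_rng(42)
        chroms = genome.chromosomes
        for _ in range(300):
            if rng.random() < 0.7:  # genuine substring
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(1, 50_000 - 60))
                query = genome.subseq(chrom, start, start + int(rng.integers(20, 60)))
            else:  # random query, usually absent
                query = "".join(rng.choice(list("ACGT"), size=25))
            assert count_genome_placements(query, genome) == brute_force_placements(
                query, genome
            ), query


class TestDeduplication:
    def _dup_pair(self):
        a = make_candidate("t85_1", left_flank="ACGTACGTAC", right_flank="TTGGCCAATT")
        b = make_candidate("t40_1", left_flank="ACGTACGTAC", right_flank="TTGGCCAATT")
        return a, b

    def test_same_tag_retained_once(self):
        a, b = self._dup_pair()
        unique, dupmap = deduplicate_candidates([[a], [b]])
        assert [c.id for c in unique] == ["t85_1"]
        assert dupmap == {"t40_1": "t85_1"}

    def test_disjoint_sets_concatenate(self):
        a, _ = self._dup_pair()
        c = make_candidate("x", pos=999, left_flank="AAAAA", right_flank="CCCCC")
        unique, dupmap = deduplicate_candidates([[a], [c]])
        assert len(unique) == 2 and not dupmap

    def test_idempotent(self):
        a, b = self._dup_pair()
        once, _ = deduplicate_candidates([[a], [b]])
        twice, _ = deduplicate_candidates([once])
        assert [c.id for c in twice] == [c.id for c in once]

    def test_same_tag_different_alleles_not_duplicates(self):
        a, _ = self._dup_pair()
        b = make_candidate("other", alt="C",
                           left_flank="ACGTACGTAC", right_flank="TTGGCCAATT")
        unique, dupmap = deduplicate_candidates([[a], [b]])
        assert len(unique) == 2


class TestTranscriptAmbiguity:
    def test_two_contigs_same_transcript_excluded(self):
        a = make_candidate("a", transcript_id="T1", source_contig="c1")
        b = make_candidate("b", pos=200, transcript_id="T1", source_contig="c2")
        report = exclude_transcript_ambiguity([a, b])
        assert report.failed == {"a", "b"}

    def test_one_contig_many_snps_retained(self):
        cands = [
            make_candidate(f"s{i}", pos=100 + i, transcript_id="T2", source_contig="c1")
            for i in range(5)
        ]
        assert exclude_transcript_ambiguity(cands).passed == {c.id for c in cands}

    def test_no_labels_vacuously_passes(self):
        cands = [make_candidate("u1"), make_candidate("u2", pos=300)]
        assert exclude_transcript_ambiguity(cands).passed == {"u1", "u2"}


class TestRuleOrderIndependence:
    def test_independent_rules_commute(self):
        """The final pass set of independent per-record rules is the same
        under any ordering."""
        rng = np.random.default_rng(55)
        cands = [
            make_candidate(
                f"c{i}", pos=100 + i,
                ref="A", alt=str(rng.choice(["T", "G", "C"])),
                left_flank="A" * int(rng.integers(30, 40)),
                right_flank="C" * int(rng.integers(30, 40)),
                dp=float(rng.integers(1, 60)), qual=float(rng.integers(10, 40)),
                gq=float(rng.integers(10, 40)), mq=float(rng.integers(20, 40)),
            )
            for i in range(100)
        ]
        rules = [
            lambda c: filter_highcov_record(c, "design")[0] == PASS,
            lambda c: not is_strand_ambiguous(c.ref, c.alt),
            lambda c: check_flank_length(c),
        ]
        import itertools
        outcomes = set()
        for perm in itertools.permutations(rules):
            surviving = [c for c in cands]
            for rule in perm:
                surviving = [c for c in surviving if rule(c)]
            outcomes.add(frozenset(c.id for c in surviving))
        assert len(outcomes) == 1
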