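"""WNS, discreteness, diagnostic calling, rollup, coverage, ordination."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquascreen.assign import assign_pairs
from aquascreen.calling import (
    ABSENT_IN_WATER,
    LinkedPair,
    call_species,
    compute_wns,
    count_discrete,
    coverage_stats,
    insert_histogram,
    interval_overlap,
    leave_one_out_water_wns,
    link_pair,
    log2_wns_matrix,
    pca_coordinates,
    rollup,
)
from aquascreen.io_core import Lineage, PipelineConfig, TaxonomyTable

from conftest import concordant_evidence, count_table, toy_taxonomy


def lp(start, end, taxon="X", accession="ACC1", score=10.0):
    return LinkedPair(taxon, accession, start, end, score)


class TestComputeWNS:
    def test_printed_formula_arithmetic(self):
        counts = count_table(
            {"s": {"X": 10}, "w1": {"X": 5}, "w2": {"X": 15}},
            {"s": 10**6, "w1": 2 * 10**6, "w2": 2 * 10**6},
        )
        result = compute_wns(counts, "s", ["w1", "w2"], "X")
        assert result.wns == pytest.approx(2.0)  # 1e-5 / 5e-6

    def test_equal_fractions_give_exactly_one(self):
        counts = count_table(
            {"s": {"X": 3}, "w1": {"X": 6}}, {"s": 7000, "w1": 14000}
        )
        assert compute_wns(counts, "s", ["w1"], "X").wns == 1.0

    def test_absent_in_water_sentinel(self):
        counts = count_table({"s": {"X": 4}, "w1": {}}, {"s": 1000, "w1": 1000})
        result = compute_wns(counts, "s", ["w1"], "X")
        assert result.wns == ABSENT_IN_WATER
        assert result.absent_in_water

    def test_absent_everywhere_is_zero(self):
        counts = count_table({"s": {}, "w1": {"Y": 1}}, {"s": 1000, "w1": 1000})
        assert compute_wns(counts, "s", ["w1"], "X").wns == 0.0

    def test_self_normalization_is_error(self):
        counts = count_table({"w1": {"X": 1}, "w2": {}}, {"w1": 10, "w2": 10})
        with pytest.raises(ValueError, match="itself"):
            compute_wns(counts, "w1", ["w1", "w2"], "X")

    def test_mixture_identity_proportional_sample_scores_one_everywhere(self):
        # sample composition = 3x the pooled water composition -> WNS 1.0 exactly
        rng = np.random.default_rng(5)
        taxa = [f"T{i}" for i in range(12)]
        waters = {f"w{j}": {t: int(rng.integers(0, 30)) for t in taxa} for j in range(4)}
        totals = {f"w{j}": 50_000 for j in range(4)}
        pooled = {t: sum(w[t] for w in waters.values()) for t in taxa}
        sample = {t: 3 * pooled[t] for t in taxa}
        counts = count_table({**waters, "s": sample}, {**totals, "s": 3 * 200_000})
        for taxon in taxa:
            if pooled[taxon] > 0:
                assert compute_wns(counts, "s", list(waters), taxon).wns == 1.0


class TestLeaveOneOutWNS:
    def test_identical_waters_score_one(self):
        per = {"X": 4, "Y": 9}
        counts = count_table({f"w{j}": dict(per) for j in range(5)},
                             {f"w{j}": 1000 for j in range(5)})
        results = leave_one_out_water_wns(counts, [f"w{j}" for j in range(5)])
        assert len(results) == 10
        assert all(r.wns == 1.0 for r in results)

    def test_taxon_in_exactly_one_water(self):
        waters = {f"w{j}": ({"X": 2} if j == 0 else {}) for j in range(5)}
        counts = count_table(waters, {f"w{j}": 1000 for j in range(5)})
        results = {r.sample: r for r in leave_one_out_water_wns(counts, list(waters))}
        assert results["w0"].wns == ABSENT_IN_WATER
        assert all(results[f"w{j}"].wns == 0.0 for j in range(1, 5))

    def test_empty_counts_empty_result(self):
        counts = count_table({}, {"w0": 10, "w1": 10})
        assert leave_one_out_water_wns(counts, ["w0", "w1"]) == []

    def test_fewer_than_two_waters_is_error(self):
        counts = count_table({}, {"w0": 10})
        with pytest.raises(ValueError):
            leave_one_out_water_wns(counts, ["w0"])


class TestLinkPair:
    def test_span_arithmetic(self):
        evidence = concordant_evidence("X", [(100, 349)])
        (pair,) = assign_pairs(evidence)
        linked = link_pair(pair)
        assert (linked.start, linked.end) == (100, 349)
        assert linked.insert_length == 250

    def test_degenerate_identical_mate_intervals(self):
        evidence = concordant_evidence("X", [(10, 109)])
        fixed = [
            a.__class__(**{**a.__dict__, "subject_interval": (10, 109)})
            for a in evidence
        ]
        (pair,) = assign_pairs(fixed)
        linked = link_pair(pair)
        assert (linked.start, linked.end) == (10, 109)
        assert linked.insert_length == 100

    def test_mates_on_different_accessions_excluded(self):
        evidence = concordant_evidence("X", [(1, 300)])
        rewritten = evidence[1].__class__(
            **{**evidence[1].__dict__, "subject_accession": "ACC2"}
        )
        (pair,) = assign_pairs([evidence[0], rewritten])
        assert link_pair(pair) is None


def oracle_max_discrete(intervals, limit=50):
    """Exhaustive maximum mutually-discrete subset via bitmask search."""
    n = len(intervals)
    conflict = [0] * n
    for i, j in combinations(range(n), 2):
        if interval_overlap(intervals[i], intervals[j]) >= limit:
            conflict[i] |= 1 << j
            conflict[j] |= 1 << i
    best = 0
    for mask in range(1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if all(conflict[i] & mask == 0 for i in members):
            best = max(best, len(members))
    return best


class TestCountDiscrete:
    @pytest.mark.parametrize(
        "intervals, expected",
        [
            ([(0, 100), (60, 160)], 2),  # overlap 41 < 50
            ([(0, 200), (0, 200), (0, 200)], 1),  # full overlap
            ([(0, 100), (52, 152), (104, 204)], 3),  # pairwise overlaps 49,49,0
            ([], 0),
            ([(0, 100), (40, 140)], 1),  # overlap 61 >= 50
        ],
    )
    def test_examples(self, intervals, expected):
        linked = [lp(a, b) for a, b in intervals]
        assert count_discrete(linked, 50) == expected

    def test_short_inserts_always_count(self):
        linked = [lp(0, 30), lp(0, 30), lp(10, 40)]
        assert count_discrete(linked, 50) == 3

    @given(st.integers(0, 10**6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        intervals = []
        for _ in range(n):
            start = int(rng.integers(0, 600))
            intervals.append((start, start + int(rng.integers(10, 400))))
        linked = [lp(a, b) for a, b in intervals]
        assert count_discrete(linked, 50) == oracle_max_discrete(intervals, 50)


class TestCallSpecies:
    WATERS = ["w1", "w2"]

    def _counts(self, sample_count, water_count, total=10_000):
        return count_table(
            {"s": {"X": sample_count}, "w1": {"X": water_count}, "w2": {}},
            {"s": total, "w1": total, "w2": total},
        )

    def test_all_four_criteria_positive(self, cfg):
        evidence = concordant_evidence(
            "X", [(1, 300), (1000, 1300), (2000, 2300)], scores=[5.0, 8.0, 90.0]
        )
        counts = self._counts(3, 1)  # wns = 3 / 0.5 = 6
        call = call_species("s", "X", evidence, counts, self.WATERS, cfg)
        assert call.verdict == "positive"
        assert all(call.criteria_passed.values())

    def test_two_discrete_pairs_fail_despite_high_wns(self, cfg):
        evidence = concordant_evidence("X", [(1, 300), (1000, 1300)])
        call = call_species("s", "X", evidence, self._counts(2, 0), self.WATERS, cfg)
        assert call.verdict == "negative"
        assert call.criteria_passed["discrete_pairs"] is False
        assert call.criteria_passed["wns"] is True  # absent in water passes

    def test_wns_below_cutoff_fails(self, cfg):
        evidence = concordant_evidence(
            "X", [(1, 300), (1000, 1300), (2000, 2300), (3000, 3300), (4000, 4300)]
        )
        counts = self._counts(5, 12)  # wns = 5 / 6 < 1
        call = call_species("s", "X", evidence, counts, self.WATERS, cfg)
        assert call.verdict == "negative"
        assert call.criteria_passed["wns"] is False

    def test_zero_score_pair_fails_strict_match_criterion(self, cfg):
        evidence = concordant_evidence(
            "X", [(1, 300), (1000, 1300), (2000, 2300)], scores=[5.0, 0.0, 9.0]
        )
        call = call_species("s", "X", evidence, self._counts(3, 1), self.WATERS, cfg)
        assert call.criteria_passed["match_score"] is False
        assert call.verdict == "negative"
        lax = PipelineConfig(match_score_diagnostic_strict=False)
        call2 = call_species("s", "X", evidence, self._counts(3, 1), self.WATERS, lax)
        assert call2.verdict == "positive"

    def test_orphan_mates_do_not_veto(self, cfg):
        evidence = concordant_evidence(
            "X", [(1, 300), (1000, 1300), (2000, 2300)]
        )
        orphan = evidence[0].__class__(
            **{**evidence[0].__dict__, "read_id": "orphan"}
        )
        call = call_species(
            "s", "X", evidence + [orphan], self._counts(3, 1), self.WATERS, cfg
        )
        assert call.verdict == "positive"

    def test_verdict_monotone_in_discrete_pairs_and_wns(self, cfg):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(1, 7))
            intervals = [(1000 * i, 1000 * i + 300) for i in range(n)]
            evidence = concordant_evidence("X", intervals, scores=5.0)
            counts = self._counts(n, int(rng.integers(0, 4)))
            base = call_species("s", "X", evidence, counts, self.WATERS, cfg)
            more = concordant_evidence(
                "X", intervals + [(1000 * n, 1000 * n + 300)], scores=5.0
            )
            richer = call_species(
                "s", "X", more, self._counts(n + 1, 0), self.WATERS, cfg
            )
            if base.positive:
                assert richer.positive


class TestRollup:
    def test_additivity_and_rollup_levels(self):
        taxonomy = toy_taxonomy()
        counts = {"10359": 3, "20001": 2, "30001": 4}
        genus = rollup(counts, taxonomy, "genus")
        assert genus == {"G1": 5, "G2": 4}
        family = rollup(counts, taxonomy, "family")
        assert family == {"FAM1": 5, "FAM2": 4}

    def test_unresolvable_goes_to_unclassified(self, caplog):
        taxonomy = toy_taxonomy()
        with caplog.at_level("WARNING", logger="aquascreen"):
            out = rollup({"10359": 1, "GHOST": 2}, taxonomy, "genus")
        assert out["unclassified"] == 2

    def test_randomized_taxonomy_matches_groupby_oracle(self):
        rng = np.random.default_rng(23)
        taxonomy = TaxonomyTable()
        counts = {}
        for i in range(40):
            species = f"S{i}"
            genus = f"G{int(rng.integers(0, 8))}"
            family = f"F{int(rng.integers(0, 3))}"
            taxonomy.lineage[species] = Lineage(species, genus, family)
            counts[species] = int(rng.integers(0, 50))
        frame = pd.DataFrame(
            {
                "species": list(counts),
                "genus": [taxonomy.lineage[s].genus_id for s in counts],
                "n": list(counts.values()),
            }
        )
        expected = frame.groupby("genus")["n"].sum().to_dict()
        assert rollup(counts, taxonomy, "genus") == expected
        assert sum(rollup(counts, taxonomy, "genus").values()) == sum(counts.values())


class TestCoverageStats:
    def test_single_read_half_genome(self):
        stats = coverage_stats([(1, 500)], 1000)
        assert stats.covered_fraction == 50.0
        assert stats.mean_depth_covered == 1.0
        assert stats.n_reads == 1

    def test_overlapping_reads_positionwise_oracle(self):
        stats = coverage_stats([(1, 100), (51, 150)], 1000)
        assert stats.covered_fraction == pytest.approx(15.0)
        assert stats.mean_depth_covered == pytest.approx(200 / 150)

    def test_no_reads(self):
        stats = coverage_stats([], 1000)
        assert (stats.covered_fraction, stats.mean_depth_covered, stats.n_reads) == (
            0.0,
            0.0,
            0,
        )

    def test_out_of_bounds_interval_is_error(self):
        with pytest.raises(ValueError):
            coverage_stats([(1, 1001)], 1000)

    def test_random_intervals_match_positionwise_counting(self):
        rng = np.random.default_rng(31)
        genome = 2000
        intervals = []
        for _ in range(40):
            start = int(rng.integers(1, genome - 100))
            intervals.append((start, start + int(rng.integers(0, 100))))
        depth = np.zeros(genome)
        for a, b in intervals:
            depth[a - 1 : b] += 1
        stats = coverage_stats(intervals, genome)
        assert stats.covered_fraction == pytest.approx(100 * (depth > 0).mean())
        assert stats.mean_depth_covered == pytest.approx(depth[depth > 0].mean())


class TestInsertHistogram:
    def test_binning(self):
        linked = [lp(0, 249), lp(100, 349), lp(20, 499)]
        hist = insert_histogram(linked, 100)
        assert hist == {200: 2, 400: 1}
        assert sum(hist.values()) == 3

    def test_empty(self):
        assert insert_histogram([], 100) == {}

    def test_simulated_normal_inserts_mode_near_mean(self):
        rng = np.random.default_rng(41)
        linked = []
        for _ in range(2000):
            insert = max(100, int(round(rng.normal(300, 30))))
            start = int(rng.integers(0, 5000))
            linked.append(lp(start, start + insert - 1))
        hist = insert_histogram(linked, 100)
        mode_bin = max(hist, key=hist.get)
        assert 250 <= mode_bin + 50 <= 350  # mode bin covers the distribution mean


def test_linked_bed_and_coverage_report_writers(tmp_path):
    from aquascreen.calling import CoverageStats, write_coverage_report, write_linked_bed

    write_linked_bed([lp(100, 349)], tmp_path / "linked.bed")
    assert (tmp_path / "linked.bed").read_text() == "ACC1\t99\t349\tX\t10\n"
    write_coverage_report({"X": CoverageStats(53.5, 2.1, 10)}, tmp_path / "cov.tsv")
    assert "X\t53.50\t2.100\t10" in (tmp_path / "cov.tsv").read_text()


class TestLog2WNSMatrix:
    def test_identity_floor_and_sentinel(self):
        table = pd.DataFrame(
            {"X": [1.0, 0.0], "Y": [8.0, ABSENT_IN_WATER]}, index=["s1", "s2"]
        )
        out = log2_wns_matrix(table, floor=2.0**-10)
        assert out.loc["s1", "X"] == 0.0
        assert out.loc["s2", "X"] == -10.0
        assert out.loc["s1", "Y"] == 3.0
        assert out.loc["s2", "Y"] == 3.0  # sentinel maps to max finite WNS

    def test_identical_wns_vectors_have_zero_pca_distance(self):
        table = pd.DataFrame(
            {"X": [2.0, 2.0, 0.5], "Y": [1.0, 1.0, 4.0], "Z": [0.0, 0.0, 1.0]},
            index=["s1", "s2", "s3"],
        )
        coords = pca_coordinates(log2_wns_matrix(table), n_components=2)
        assert np.allclose(coords.loc["s1"], coords.loc["s2"])
        assert not np.allclose(coords.loc["s1"], coords.loc["s3"])
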