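import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvquartet import (
    CallSet,
    CNVCall,
    GenomeContext,
    Status,
    callset_stats,
    merge_adjacent,
    merged_fraction,
    reciprocal_overlap,
    ro_match,
)
from cnvquartet.cnv_core import ROIndex, union_covered_bases

from conftest import TINY_GENOME, call
from oracles import brute_coverage, brute_merge, brute_ro, random_calls

intervals = st.tuples(
    st.integers(0, 5_000), st.integers(1, 500)
).map(lambda t: (t[0], t[0] + t[1]))


class TestReciprocalOverlap:
    def test_half_overlap(self):
        ro = reciprocal_overlap(call("1", 100, 200), call("1", 150, 250))
        assert (ro.r_a, ro.r_b) == (0.5, 0.5)

    def test_identical_calls(self):
        ro = reciprocal_overlap(call("1", 100, 200), call("1", 100, 200))
        assert (ro.r_a, ro.r_b) == (1.0, 1.0)

    def test_different_chromosomes(self):
        ro = reciprocal_overlap(call("1", 0, 100), call("2", 0, 100))
        assert (ro.r_a, ro.r_b) == (0.0, 0.0)

    @given(a=intervals, b=intervals)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, a, b):
        ca, cb = call("1", *a), call("1", *b)
        ro, rev = reciprocal_overlap(ca, cb), reciprocal_overlap(cb, ca)
        assert (ro.r_a, ro.r_b) == (rev.r_b, rev.r_a)
        assert 0 <= ro.r_a <= 1 and 0 <= ro.r_b <= 1


class TestROMatch:
    @pytest.mark.parametrize(
        "b,expected",
        [(call("1", 150, 250), False),  # min RO 0.5 < 0.7
         (call("1", 110, 210), True),   # overlap 90, min RO 0.9
         (call("1", 100, 200, Status.LOSS), False)],  # status mismatch
    )
    def test_seventy_percent_examples(self, b, expected):
        assert ro_match(call("1", 100, 200), b, 0.70) is expected

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            ro_match(call("1", 0, 10), call("1", 0, 10), 0.0)
        with pytest.raises(ValueError):
            ro_match(call("1", 0, 10), call("1", 0, 10), 1.5)

    @given(a=intervals, b=intervals,
           t1=st.floats(0.05, 1.0), t2=st.floats(0.05, 1.0))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_symmetric_and_monotone_in_threshold(self, a, b, t1, t2):
        ca, cb = call("1", *a), call("1", *b)
        lo, hi = min(t1, t2), max(t1, t2)
        assert ro_match(ca, cb, lo) == ro_match(cb, ca, lo)
        if ro_match(ca, cb, hi):
            assert ro_match(ca, cb, lo)

    def test_agrees_with_brute_force(self, rng):
        calls = random_calls(rng, 40, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall)
        for i in range(0, 40, 2):
            a, b = calls[i], calls[i + 1]
            ro = reciprocal_overlap(a, b)
            assert (ro.r_a, ro.r_b) == pytest.approx(brute_ro(a, b))


class TestMergeAdjacent:
    def test_small_gap_merges(self):
        cs = CallSet.from_iter([call("1", 100, 200), call("1", 204, 300)])
        merged = merge_adjacent(cs, 5000)
        assert [(c.start, c.end) for c in merged] == [(100, 300)]

    def test_large_gap_does_not_merge(self):
        cs = CallSet.from_iter([call("1", 100, 200), call("1", 5300, 5400)])
        assert len(merge_adjacent(cs, 5000)) == 2

    def test_gap_exactly_at_threshold_not_merged(self):
        # "separated by less than 5 kb": a 5000 bp gap stays unmerged
        cs = CallSet.from_iter([call("1", 0, 100), call("1", 5100, 5200)])
        assert len(merge_adjacent(cs, 5000)) == 2

    def test_opposite_status_never_merged(self):
        cs = CallSet.from_iter(
            [call("1", 0, 100), call("1", 50, 150, Status.LOSS)]
        )
        assert len(merge_adjacent(cs, 5000)) == 2

    def test_matches_union_find_oracle_and_is_idempotent(self, rng):
        for gap in (500, 5000):
            for _ in range(10):
                calls = random_calls(
                    rng, 50, {"1": 40_000}, [Status.GAIN], CNVCall, max_size=1_500
                )
                cs = CallSet.from_iter(calls)
                merged = merge_adjacent(cs, gap)
                assert {c.key for c in merged} == {
                    k[:3] + (k[3],) for k in brute_merge(list(cs), gap)
                }
                assert merge_adjacent(merged, gap) == merged

    def test_never_decreases_coverage_nor_increases_count(self, rng):
        calls = random_calls(
            rng, 80, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall
        )
        cs = CallSet.from_iter(calls)
        merged = merge_adjacent(cs, 2_000)
        assert len(merged) <= len(cs)
        assert union_covered_bases(merged) >= union_covered_bases(cs)


class TestMergedFraction:
    def test_no_merges(self):
        cs = CallSet.from_iter([call("1", 0, 100), call("1", 20_000, 20_100)])
        assert merged_fraction(cs, 5000) == 0.0

    def test_full_chain(self):
        cs = CallSet.from_iter(
            [call("1", i * 1000, i * 1000 + 500) for i in range(5)]
        )
        assert merged_fraction(cs, 5000) == 1.0

    def test_two_of_four_affected(self):
        cs = CallSet.from_iter(
            [call("1", 0, 100), call("1", 200, 300),
             call("1", 50_000, 50_100), call("2", 0, 100)]
        )
        assert merged_fraction(cs, 5000) == 0.5

    def test_empty_callset(self):
        assert merged_fraction(CallSet.from_iter([])) == 0.0


class TestCallsetStats:
    def test_forced_arithmetic(self):
        ctx = GenomeContext(chrom_lengths={"1": 1000})
        cs = CallSet.from_iter([call("1", 0, 100), call("1", 300, 400)])
        s = callset_stats(cs, ctx)
        assert (s.n_calls, s.mean_size, s.mean_adjacent_distance, s.genome_coverage) == (
            2, 100, 200, 0.2
        )

    def test_whole_chromosome_coverage(self):
        ctx = GenomeContext(chrom_lengths={"1": 5000})
        s = callset_stats(CallSet.from_iter([call("1", 0, 5000)]), ctx)
        assert s.genome_coverage == 1.0
        assert s.mean_adjacent_distance is None  # single call: no adjacency

    def test_overlapping_opposite_status_gap_clamped(self):
        ctx = GenomeContext(chrom_lengths={"1": 10_000})
        cs = CallSet.from_iter(
            [call("1", 0, 1000), call("1", 500, 1500, Status.LOSS)]
        )
        assert callset_stats(cs, ctx).mean_adjacent_distance == 0

    def test_coverage_matches_bitmap_oracle(self, rng):
        ctx = GenomeContext(chrom_lengths=dict(TINY_GENOME))
        calls = random_calls(rng, 200, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall)
        cs = CallSet.from_iter(calls)
        s = callset_stats(cs, ctx)
        assert s.genome_coverage == pytest.approx(brute_coverage(calls, TINY_GENOME))

    def test_call_beyond_chromosome_rejected(self):
        ctx = GenomeContext(chrom_lengths={"1": 100})
        with pytest.raises(ValueError):
            callset_stats(CallSet.from_iter([call("1", 0, 200)]), ctx)


class TestROIndex:
    def test_matches_all_pairs_scan(self, rng):
        a = random_calls(rng, 60, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall)
        b = random_calls(rng, 60, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall)
        index = ROIndex(CallSet.from_iter(b), 0.5)
        for c in a:
            expected = sorted(
                x.key for x in b if ro_match(c, x, 0.5)
            )
            assert sorted(x.key for x in index.matches(c)) == expected
            assert index.has_match(c) == bool(expected)
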