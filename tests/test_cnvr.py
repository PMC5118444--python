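"""CNVR construction: reciprocal overlap, merging, filtering, states, summaries."""

import numpy as np
import pytest

from cnvrkit.cnvr import (
    CnvCall,
    CnvrRegion,
    classify_state,
    compare_cnvr_sets,
    filter_by_frequency,
    merge_cnvs,
    reciprocal_overlap,
    summarize_cnvrs,
)

from conftest import merge_oracle


def call(sample, chrom, start, end, cn=1):
    return CnvCall(sample, chrom, start, end, cn)


def random_calls(rng, n, chrom="1", span=1000):
    calls = []
    for i in range(n):
        s = int(rng.integers(0, span))
        length = int(rng.integers(1, span // 3))
        calls.append(call(f"S{i}", chrom, s, s + length, cn=int(rng.integers(0, 2))))
    return calls


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("1", 100, 200), ("1", 140, 240), 0.6),
            (("1", 100, 200), ("1", 100, 200), 1.0),
            (("1", 0, 100), ("1", 100, 200), 0.0),  # half-open adjacency
            (("1", 0, 100), ("2", 0, 100), 0.0),  # different chromosomes
            (("1", 0, 100), ("1", 25, 75), 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)

    def test_symmetric(self, rng):
        for _ in range(100):
            s1, s2 = rng.integers(0, 500, size=2)
            l1, l2 = rng.integers(1, 300, size=2)
            a, b = ("1", int(s1), int(s1 + l1)), ("1", int(s2), int(s2 + l2))
            assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(("1", 100, 100), ("1", 0, 50))


class TestMerge:
    def test_two_overlapping_calls_merge_to_spanning_region(self):
        # a < c < b < d with reciprocal overlap >= 0.5: one region from a to d
        a, b, c, d = 100, 200, 140, 240
        regions = merge_cnvs([call("S1", "1", a, b), call("S2", "1", c, d)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (a, d)
        assert regions[0].n_samples == 2

    def test_single_call_is_its_own_region(self):
        regions = merge_cnvs([call("S1", "1", 5, 50)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (5, 50)

    def test_below_threshold_calls_stay_separate(self):
        regions = merge_cnvs([call("S1", "1", 0, 100), call("S2", "1", 60, 160)])
        assert len(regions) == 2

    def test_exact_threshold_boundary_merges(self):
        # overlap 50 over both lengths 100: exactly 0.5, must merge (>=)
        regions = merge_cnvs([call("S1", "1", 0, 100), call("S2", "1", 50, 150)])
        assert len(regions) == 1

    def test_partition_property(self, rng):
        calls = random_calls(rng, 30)
        regions = merge_cnvs(calls)
        assert sum(len(r.members) for r in regions) == len(calls)
        assert sorted(m for r in regions for m in r.members) == sorted(calls)

    def test_permutation_invariance(self, rng):
        calls = random_calls(rng, 15)
        ref = merge_cnvs(calls)
        for _ in range(5):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            assert merge_cnvs(perm) == ref

    def test_idempotent_on_emitted_extents(self, rng):
        calls = random_calls(rng, 20)
        regions = merge_cnvs(calls)
        pseudo = [call(f"R{i}", r.chrom, r.start, r.end) for i, r in enumerate(regions)]
        again = merge_cnvs(pseudo)
        assert [(r.chrom, r.start, r.end) for r in again] == [
            (r.chrom, r.start, r.end) for r in regions
        ]

    @pytest.mark.parametrize("threshold", [0.3, 0.5, 0.8])
    def test_matches_fixed_point_oracle(self, rng, threshold):
        for _ in range(50):
            calls = random_calls(rng, int(rng.integers(1, 21)))
            regions = merge_cnvs(calls, threshold=threshold)
            got = {(r.chrom, r.start, r.end, frozenset(r.members)) for r in regions}
            assert got == merge_oracle(calls, threshold)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            merge_cnvs([call("S1", "1", 0, 10)], threshold=0.0)


class TestFrequencyFilter:
    def test_split_by_distinct_samples(self):
        r2 = merge_cnvs([call("S1", "1", 0, 100), call("S2", "1", 10, 110)])[0]
        r3 = merge_cnvs(
            [call("S1", "2", 0, 100), call("S2", "2", 10, 110), call("S3", "2", 5, 105)]
        )[0]
        kept, removed = filter_by_frequency([r2, r3], min_samples=3)
        assert kept == [r3]
        assert removed == [r2]

    def test_counts_samples_not_calls(self):
        # one sample contributing two calls still counts once
        r = CnvrRegion(
            "1", 0, 110, tuple(sorted([call("S1", "1", 0, 100), call("S1", "1", 10, 110)]))
        )
        kept, removed = filter_by_frequency([r], min_samples=2)
        assert kept == [] and removed == [r]


class TestClassifyState:
    def test_all_below_baseline_is_loss(self, genome):
        r = merge_cnvs([call("S1", "1", 0, 100, 0), call("S2", "1", 5, 105, 1)])[0]
        assert classify_state(r, genome) == "loss"

    def test_all_above_baseline_is_gain(self, genome):
        r = merge_cnvs([call("S1", "1", 0, 100, 3), call("S2", "1", 5, 105, 4)])[0]
        assert classify_state(r, genome) == "gain"

    def test_both_directions_is_mixed(self, genome):
        r = merge_cnvs([call("S1", "1", 0, 100, 1), call("S2", "1", 5, 105, 3)])[0]
        assert classify_state(r, genome) == "mixed"

    def test_x_chromosome_uses_its_own_baseline(self, genome):
        # CN=2 on a ploidy-1 X is a gain
        r = merge_cnvs([call("S1", "X", 0, 100, 2)])[0]
        assert classify_state(r, genome) == "gain"

    def test_baseline_copy_number_member_rejected(self, genome):
        r = merge_cnvs([call("S1", "1", 0, 100, 2)])[0]
        with pytest.raises(ValueError, match="baseline"):
            classify_state(r, genome)

    def test_trichotomy(self, genome, rng):
        for _ in range(20):
            cns = rng.choice([0, 1, 3, 4], size=int(rng.integers(1, 6)))
            calls = [call(f"S{i}", "1", 0, 100, int(cn)) for i, cn in enumerate(cns)]
            r = merge_cnvs(calls)[0]
            assert classify_state(r, genome) in ("loss", "gain", "mixed")


class TestSummarize:
    def _region(self, chrom, start, end, state="loss", cn=0):
        r = merge_cnvs([call("S1", chrom, start, end, cn)])[0]
        from dataclasses import replace

        return replace(r, state=state)

    def test_size_statistics(self, genome):
        cnvrs = [self._region("1", 0, 100), self._region("1", 500, 800)]
        s = summarize_cnvrs(cnvrs, genome)
        assert s.mean_size == 200 and s.median_size == 200
        assert s.min_size == 100 and s.max_size == 300

    def test_unique_coverage_is_a_union(self, genome):
        cnvrs = [self._region("1", 0, 100), self._region("1", 50, 150)]
        s = summarize_cnvrs(cnvrs, genome)
        assert s.total_unique == 150
        assert s.genome_fraction == pytest.approx(150 / 1_900_000)

    def test_unique_coverage_matches_bitmap_oracle(self, genome, rng):
        cnvrs = []
        for _ in range(50):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(1, 500))
            cnvrs.append(self._region("1", s, e))
        summary = summarize_cnvrs(cnvrs, genome)
        bitmap = np.zeros(6000, dtype=bool)
        for r in cnvrs:
            bitmap[r.start : r.end] = True
        assert summary.total_unique == int(bitmap.sum())

    def test_state_counts_partition_the_set(self, genome):
        cnvrs = [
            self._region("1", 0, 100, "loss"),
            self._region("1", 500, 600, "gain", cn=3),
            self._region("2", 0, 100, "mixed"),
        ]
        s = summarize_cnvrs(cnvrs, genome)
        assert s.state_counts == {"loss": 1, "gain": 1, "mixed": 1}
        assert sum(s.state_counts.values()) == s.count

    def test_region_beyond_chromosome_rejected(self, genome):
        with pytest.raises(ValueError, match="beyond"):
            summarize_cnvrs([self._region("2", 0, 600_000)], genome)


class TestCompareSets:
    def test_contained_query_counts_as_overlapped(self):
        q = [merge_cnvs([call("S1", "1", 10, 20)])[0]]
        assert compare_cnvr_sets(q, [("1", 0, 100)]) == 1.0

    def test_abutting_half_open_intervals_do_not_overlap(self):
        q = [merge_cnvs([call("S1", "1", 0, 100)])[0]]
        assert compare_cnvr_sets(q, [("1", 100, 200)]) == 0.0

    def test_fraction_matches_per_base_oracle(self, rng):
        query = [merge_cnvs([call("S1", "1", int(s), int(s) + int(l))])[0]
                 for s, l in zip(rng.integers(0, 900, 20), rng.integers(1, 100, 20))]
        reference = [("1", int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 900, 10), rng.integers(1, 100, 10))]
        ref_bases = set()
        for _, s, e in reference:
            ref_bases.update(range(s, e))
        expected = sum(
            1 for r in query if ref_bases.intersection(range(r.start, r.end))
        ) / len(query)
        assert compare_cnvr_sets(query, reference) == pytest.approx(expected)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            compare_cnvr_sets([], [("1", 0, 10)])
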