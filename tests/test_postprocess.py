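"""Duplicate removal, fragment merging, and segment geometry."""

import itertools
import math

import numpy as np
import pytest

from cellhough import (included_angle, merge_fragments, polyline_length,
                       remove_duplicates, segment_min_distance)
from cellhough.postprocess import PolylineCell
from conftest import make_segment


def sampling_distance_oracle(a, b, n=250):
    """Dense-sampling minimum distance between two segments."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    pa = np.array(a.start) + t * (np.array(a.end) - np.array(a.start))
    pb = np.array(b.start) + t * (np.array(b.end) - np.array(b.start))
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return d.min()


def random_segment(rng, box=100.0, min_len=5.0, max_len=40.0):
    while True:
        x1, y1 = rng.uniform(0, box, 2)
        ang = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(min_len, max_len)
        x2 = x1 + length * math.cos(ang)
        y2 = y1 + length * math.sin(ang)
        if 0 <= x2 <= box and 0 <= y2 <= box:
            return make_segment(x1, y1, x2, y2)


class TestSegmentMinDistance:
    def test_identical_segments_have_zero_distance(self):
        a = make_segment(0, 0, 10, 0)
        assert segment_min_distance(a, a) == 0.0

    def test_parallel_offset_is_the_offset(self):
        a = make_segment(0, 0, 20, 0)
        b = make_segment(5, 10, 15, 10)
        assert segment_min_distance(a, b) == pytest.approx(10.0)

    def test_crossing_segments_have_zero_distance(self):
        a = make_segment(0, 0, 10, 10)
        b = make_segment(0, 10, 10, 0)
        assert segment_min_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_matches_sampling_oracle(self, rng):
        for _ in range(20):
            a, b = random_segment(rng), random_segment(rng)
            d = segment_min_distance(a, b)
            assert d == pytest.approx(segment_min_distance(b, a))
            assert abs(d - sampling_distance_oracle(a, b)) <= 0.1


class TestIncludedAngle:
    def test_parallel_is_zero_and_perpendicular_is_ninety(self):
        a = make_segment(0, 0, 10, 0)
        b = make_segment(0, 5, 10, 5)
        c = make_segment(3, 0, 3, 10)
        assert included_angle(a, b) == pytest.approx(0.0, abs=1e-9)
        assert included_angle(a, c) == pytest.approx(90.0)

    def test_undirected_wraparound(self):
        a = make_segment(0, 0, math.cos(math.radians(10)),
                         math.sin(math.radians(10)))
        b = make_segment(0, 0, math.cos(math.radians(170)),
                         math.sin(math.radians(170)))
        assert included_angle(a, b) == pytest.approx(20.0, abs=1e-6)

    def test_degenerate_segment_raises(self):
        from cellhough import LineSegment
        point = LineSegment(start=(1.0, 1.0), end=(1.0, 1.0),
                            theta=0.0, rho=1.0)
        with pytest.raises(ValueError):
            included_angle(point, make_segment(0, 0, 5, 0))


def exhaustive_dedup_oracle(segs, dist_thresh=15.0, angle_thresh=20.0):
    """Enumerate every conflict-free subset and keep the one whose
    descending length sequence is lexicographically largest (removal
    always sacrifices the shorter member of a conflict)."""
    n = len(segs)
    conflict = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        conflict[i, j] = conflict[j, i] = (
            segment_min_distance(segs[i], segs[j]) < dist_thresh
            and included_angle(segs[i], segs[j]) < angle_thresh
        )
    best, best_key = None, None
    for mask in range(1, 2 ** n):
        members = [i for i in range(n) if mask >> i & 1]
        if any(conflict[i, j] for i, j in
               itertools.combinations(members, 2)):
            continue
        key = sorted((segs[i].length for i in members), reverse=True)
        if best_key is None or _lex_greater(key, best_key):
            best, best_key = members, key
    return {id(segs[i]) for i in best}


def _lex_greater(a, b):
    for x, y in itertools.zip_longest(a, b, fillvalue=-math.inf):
        if x != y:
            return x > y
    return False


class TestRemoveDuplicates:
    def test_close_parallel_pair_keeps_the_longer(self):
        long = make_segment(0, 0, 30, 0)
        short = make_segment(2, 10, 27, 10)  # distance 10, angle 0
        assert remove_duplicates([short, long]) == [long]

    def test_pair_just_beyond_distance_threshold_survives(self):
        long = make_segment(0, 0, 30, 0)
        short = make_segment(2, 16, 27, 16)  # distance 16 >= 15
        assert set(remove_duplicates([short, long])) == {short, long}

    def test_pair_beyond_angle_threshold_survives(self):
        a = make_segment(0, 0, 30, 0)
        b = make_segment(0, 5, 30 * math.cos(math.radians(25)),
                         5 + 30 * math.sin(math.radians(25)))
        assert included_angle(a, b) == pytest.approx(25.0, abs=1e-6)
        assert set(remove_duplicates([a, b])) == {a, b}

    def test_distance_exactly_at_threshold_survives(self):
        """The rule is strict: exactly 15 px is not "fewer than 15"."""
        a = make_segment(0, 0, 30, 0)
        at_dist = make_segment(0, 15, 25, 15)
        assert segment_min_distance(a, at_dist) == 15.0
        assert set(remove_duplicates([a, at_dist])) == {a, at_dist}

    def test_idempotent_and_never_grows(self, rng):
        segs = [random_segment(rng) for _ in range(12)]
        once = remove_duplicates(segs)
        assert len(once) <= len(segs)
        assert remove_duplicates(once) == once

    def test_order_independent(self, rng):
        segs = [random_segment(rng) for _ in range(10)]
        ref = set(remove_duplicates(segs))
        for _ in range(5):
            perm = list(segs)
            rng.shuffle(perm)
            assert set(remove_duplicates(perm)) == ref

    def test_agrees_with_exhaustive_oracle(self, rng):
        """On every random conflict graph of up to 8 segments the greedy
        result equals the lexicographically length-favoring maximal
        conflict-free set."""
        for n in range(2, 9):
            for _ in range(4):
                segs = [random_segment(rng, box=60.0) for _ in range(n)]
                kept = {id(s) for s in remove_duplicates(segs)}
                assert kept == exhaustive_dedup_oracle(segs)


class TestMergeFragments:
    def test_shared_endpoint_becomes_one_piecewise_cell(self):
        a = make_segment(0, 0, 20, 0)
        b = make_segment(20, 0, 35, 10)
        cells = merge_fragments([a, b])
        assert len(cells) == 1
        expected = 20.0 + math.hypot(15, 10)
        assert cells[0].total_length == pytest.approx(expected)

    def test_distant_segments_stay_separate(self):
        a = make_segment(0, 0, 20, 0)
        b = make_segment(0, 100, 20, 100)
        cells = merge_fragments([a, b])
        assert len(cells) == 2
        assert all(len(c.segments) == 1 for c in cells)

    def test_chain_of_three_merges_transitively(self):
        a = make_segment(0, 0, 20, 0)
        b = make_segment(20, 0, 30, 10)
        c = make_segment(30, 10, 50, 12)
        cells = merge_fragments([a, b, c])
        assert len(cells) == 1
        assert len(cells[0].segments) == 3

    def test_close_endpoints_merge_within_tolerance(self):
        a = make_segment(0, 0, 20, 0)
        b = make_segment(24, 0, 40, 0)  # 4 px endpoint gap
        assert len(merge_fragments([a, b], join_tol=5.0)) == 1
        assert len(merge_fragments([a, b], join_tol=3.0)) == 2

    def test_total_length_conserved_and_count_never_grows(self, rng):
        segs = [random_segment(rng) for _ in range(15)]
        cells = merge_fragments(segs)
        assert len(cells) <= len(segs)
        assert sum(c.total_length for c in cells) == pytest.approx(
            sum(s.length for s in segs))


class TestPolylineLength:
    def test_known_lengths(self):
        assert polyline_length(PolylineCell(
            [make_segment(0, 0, 30, 0)])) == pytest.approx(30.0)
        assert polyline_length(PolylineCell(
            [make_segment(0, 0, 3, 4)])) == pytest.approx(5.0)
        l_shape = PolylineCell([make_segment(0, 0, 20, 0),
                                make_segment(20, 0, 20, 20)])
        assert polyline_length(l_shape) == pytest.approx(40.0)

    def test_empty_polyline_is_rejected(self):
        with pytest.raises(ValueError):
            PolylineCell(segments=[])
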