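import numpy as np
import pytest

from dermoborder import borderline as bl
from dermoborder.detect import turning_points

from conftest import disc_mask, ellipse_mask


def square_mask(lo=10, hi=31, n=41):
    m = np.zeros((n, n), bool)
    m[lo:hi, lo:hi] = True
    return m


class TestTraceBoundary:
    def test_single_pixel_trace(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        trace = bl.trace_boundary(m)
        assert trace.shape == (1, 2)
        assert tuple(trace[0]) == (2, 3)

    def test_three_by_three_square_clockwise(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        trace = bl.trace_boundary(m)
        expected = [(1, 1), (1, 2), (1, 3), (2, 3), (3, 3), (3, 2), (3, 1), (2, 1)]
        assert [tuple(p) for p in trace] == expected

    def test_disc_trace_length_matches_boundary_pixel_count(self):
        m = disc_mask(50)
        trace = bl.trace_boundary(m)
        from scipy import ndimage as ndi

        cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
        boundary = m & ~ndi.binary_erosion(m, structure=cross)
        assert abs(len(trace) - boundary.sum()) <= 0.05 * boundary.sum()

    def test_trace_is_closed_and_8_adjacent(self):
        m = ellipse_mask(40, 25)
        trace = bl.trace_boundary(m)
        steps = np.abs(np.diff(np.vstack([trace, trace[:1]]), axis=0))
        assert steps.max() <= 1  # consecutive points are 8-adjacent, closed
        assert len(np.unique(trace, axis=0)) == len(trace)  # no repeats

    def test_empty_mask_raises(self):
        with pytest.raises(bl.BorderlineError):
            bl.trace_boundary(np.zeros((4, 4), bool))


class TestSplitQuadrants:
    def test_square_splits_at_corners(self):
        m = square_mask()
        trace = bl.trace_boundary(m)
        split = bl.split_quadrants(trace, m)
        corners = {tuple(trace[i]) for i in split.split_indices}
        assert corners == {(10, 10), (10, 30), (30, 30), (30, 10)}

    def test_disc_segments_cover_ninety_degrees_each(self):
        m = disc_mask(60)
        trace = bl.trace_boundary(m)
        split = bl.split_quadrants(trace, m)
        c = np.array(split.centroid)
        for which in bl.SIDES:
            seg = split.segment(trace, which)
            v0 = seg[0] - c
            v1 = seg[-1] - c
            ang = np.degrees(
                np.arccos(
                    np.clip(v0 @ v1 / (np.linalg.norm(v0) * np.linalg.norm(v1)), -1, 1)
                )
            )
            assert ang == pytest.approx(90.0, abs=2.0)

    def test_wide_ellipse_has_longer_top_and_bottom_segments(self):
        m = ellipse_mask(80, 40)
        trace = bl.trace_boundary(m)
        split = bl.split_quadrants(trace, m)
        lengths = [stop - start for start, stop in split.ranges]
        top, right, bottom, left = lengths
        assert top > right and top > left
        assert bottom > right and bottom > left

    def test_segments_partition_the_trace_exactly(self):
        for m in (square_mask(), disc_mask(35), ellipse_mask(55, 30)):
            trace = bl.trace_boundary(m)
            split = bl.split_quadrants(trace, m)
            total = sum(stop - start for start, stop in split.ranges)
            assert total == len(trace)
            covered = np.concatenate(
                [np.arange(start, stop) % len(trace) for start, stop in split.ranges]
            )
            assert len(np.unique(covered)) == len(trace)


class TestSegmentProfile:
    def test_square_top_side_is_constant(self):
        m = square_mask()
        trace = bl.trace_boundary(m)
        split = bl.split_quadrants(trace, m)
        prof = bl.segment_profile(split.segment(trace, "top"), "top", m.shape)
        inner = prof.values[1:-1]  # corners themselves start the descent
        assert np.ptp(inner) == 0.0

    def test_single_column_spike_appears_at_full_height(self):
        m = square_mask(lo=12, hi=33, n=45)
        m[4:12, 22] = True  # 8-px spike out of the top side
        trace = bl.trace_boundary(m)
        split = bl.split_quadrants(trace, m)
        prof = bl.segment_profile(split.segment(trace, "top"), "top", m.shape)
        idx, proms = turning_points(prof.values, 0.0)
        assert len(idx) == 1
        assert proms[0] == 8.0

    def test_disc_segment_has_a_single_interior_maximum(self):
        m = disc_mask(45)
        trace = bl.trace_boundary(m)
        split = bl.split_quadrants(trace, m)
        for which in bl.SIDES:
            prof = bl.segment_profile(split.segment(trace, which), which, m.shape)
            idx, _ = turning_points(prof.values, 0.0)
            assert len(idx) == 1

    def test_every_side_raises_on_empty_segment(self):
        with pytest.raises(bl.BorderlineError):
            bl.segment_profile(np.empty((0, 2), int), "top", (10, 10))


class TestAssemble:
    def test_four_constant_profiles_assemble_to_a_constant(self):
        profiles = [
            bl.SegmentProfile(
                values=np.full(n, h, dtype=float),
                coords=np.zeros((n, 2), int),
                side=side,
                overhangs=0,
            )
            for side, h, n in zip(bl.SIDES, [10.0, 40.0, 25.0, 90.0], [7, 5, 9, 6])
        ]
        sig = bl.assemble_borderline(profiles)
        assert np.allclose(sig.values, 10.0)
        assert len(sig) == 7 + 5 + 9 + 6

    def test_junction_discontinuities_are_zero(self):
        sig = bl.borderline_from_mask(ellipse_mask(60, 35))
        for j in sig.junctions:
            # the incoming segment is shifted to meet the previous one exactly
            assert sig.values[j] == sig.values[j - 1]

    def test_disc_signal_has_exactly_four_maxima_before_smoothing(self):
        sig = bl.borderline_from_mask(disc_mask(50))
        idx, _ = turning_points(sig.values, 0.0)
        assert len(idx) == 4

    def test_signal_length_equals_sum_of_profiles(self):
        m = ellipse_mask(60, 35)
        trace = bl.trace_boundary(m)
        sig = bl.borderline_from_mask(m)
        assert len(sig) == len(trace)
        assert len(sig.coords) == len(sig)
        assert len(sig.segment_labels) == len(sig)
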