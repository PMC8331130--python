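import math

import numpy as np
import pytest

from gridfree.segmentation import (
    Segment,
    SegmentSet,
    SegmentThresholds,
    connected_components,
    estimate_count,
    expand_merge,
    peel_once,
    prune_lower,
    segment_pipeline,
    shrink_boundary,
    watershed_split,
)
from helpers import disk_mask, union_find_components


class TestConnectedComponents:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 3] = 1
        segs = connected_components(m)
        assert len(segs) == 1
        seg = segs.segments[0]
        assert seg.area == 1
        assert seg.diagonal == pytest.approx(math.sqrt(2))

    def test_diagonal_touch_is_one_component(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[1, 1] = m[2, 2] = 1
        assert len(connected_components(m)) == 1

    def test_empty_mask(self):
        assert len(connected_components(np.zeros((3, 3), dtype=np.uint8))) == 0

    def test_ids_in_raster_order_of_first_pixel(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[0, 4] = 1
        m[3, 0] = 1
        m[5, 5] = 1
        segs = connected_components(m)
        firsts = [s.first_pixel for s in segs]
        assert firsts == sorted(firsts)
        assert [s.id for s in segs] == [1, 2, 3]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_union_find_oracle(self, trial):
        rng = np.random.default_rng(trial)
        m = (rng.random((64, 64)) < 0.45).astype(np.uint8)
        ours = {frozenset(s.pixel_set()) for s in connected_components(m)}
        assert ours == union_find_components(m)


class TestPruneLower:
    def _segs(self):
        m = np.zeros((10, 20), dtype=np.uint8)
        m[1, 1] = 1                 # speck, area 1
        m[4:6, 4:8] = 1             # area 8
        m[8, 10:18] = 1             # thin line, area 8, diag ~8
        return connected_components(m)

    def test_zero_bounds_are_identity(self):
        segs = self._segs()
        assert len(prune_lower(segs, SegmentThresholds())) == len(segs)

    def test_single_speck_removed(self):
        m = np.zeros((3, 3), dtype=np.uint8)
        m[1, 1] = 1
        out = prune_lower(connected_components(m), SegmentThresholds(area_min=2))
        assert len(out) == 0

    def test_matches_filter_oracle(self):
        segs = self._segs()
        t = SegmentThresholds(area_min=5, diag_min=5)
        out = prune_lower(segs, t)
        expected = {
            frozenset(s.pixel_set())
            for s in segs
            if s.area >= 5 and s.diagonal >= 5
        }
        assert {frozenset(s.pixel_set()) for s in out} == expected


class TestEstimateCount:
    @pytest.mark.parametrize(
        "area,mean,expected",
        [(300, 100.0, 3), (250, 100.0, 3), (120, 100.0, 2), (1000, 99.0, 10)],
    )
    def test_rounding_and_floor(self, area, mean, expected):
        assert estimate_count(area, mean) == expected

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            estimate_count(100, 0.0)


class TestWatershedSplit:
    def test_fused_disks_split_along_bisector(self):
        c1, c2 = (20, 23), (20, 37)
        m = disk_mask((40, 60), [c1, c2], 8)
        seg = connected_components(m).segments[0]
        kids = watershed_split(seg, mean_area=math.pi * 64, target=2)
        assert len(kids) == 2
        assert sum(k.area for k in kids) == seg.area
        for k in kids:
            d1 = np.hypot(k.rows - c1[0], k.cols - c1[1])
            d2 = np.hypot(k.rows - c2[0], k.cols - c2[1])
            own_first = (d1 < d2).mean() > 0.5
            margin = (d2 - d1) if own_first else (d1 - d2)
            # pixel assignment deviates from the perpendicular-bisector
            # oracle only inside a 2-px band around the bisector
            assert np.all(margin >= -2.0)
        # exactly one true center per child
        owns = [
            any((r, c) == c1 for r, c in k.pixel_set())
            + any((r, c) == c2 for r, c in k.pixel_set())
            for k in kids
        ]
        assert sorted(owns) == [1, 1]

    def test_single_disk_is_unsplittable(self):
        m = disk_mask((40, 40), [(20, 20)], 8)
        seg = connected_components(m).segments[0]
        kids = watershed_split(seg, mean_area=math.pi * 64, target=2)
        assert len(kids) == 1
        assert kids[0].note == "unsplittable"
        assert kids[0].area == seg.area

    def test_chain_of_three_disks(self):
        m = disk_mask((40, 80), [(20, 20), (20, 34), (20, 48)], 8)
        seg = connected_components(m).segments[0]
        one_disk = float(disk_mask((40, 40), [(20, 20)], 8).sum())
        kids = watershed_split(seg, mean_area=one_disk, target=3)
        assert len(kids) == 3
        for k in kids:
            assert abs(k.area - one_disk) / one_disk < 0.2

    def test_deterministic_across_runs(self):
        m = disk_mask((40, 60), [(20, 23), (20, 37)], 8)
        seg = connected_components(m).segments[0]
        a = watershed_split(seg, math.pi * 64, 2)
        b = watershed_split(seg, math.pi * 64, 2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.rows, y.rows)
            np.testing.assert_array_equal(x.cols, y.cols)

    def test_invalid_arguments_rejected(self):
        seg = connected_components(disk_mask((20, 20), [(10, 10)], 5)).segments[0]
        with pytest.raises(ValueError):
            watershed_split(seg, 10.0, 1)
        with pytest.raises(ValueError):
            watershed_split(seg, 0.0, 2)


def bridge_fixture():
    """Two 5x5 squares joined by a 1-px-wide, 3-px-long bridge (5x13 grid)."""
    m = np.zeros((5, 13), dtype=np.uint8)
    m[0:5, 0:5] = 1
    m[0:5, 8:13] = 1
    m[2, 5:8] = 1
    return m


class TestShrinkBoundary:
    def test_3x3_square_peels_to_center_in_one_iteration(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        peeled = peel_once(m)
        assert peeled.sum() == 1 and peeled[2, 2]

    def test_bridge_fixture_splits_into_two_conserving_pixels(self):
        m = bridge_fixture()
        seg = connected_components(m).segments[0]
        kids = shrink_boundary(seg, SegmentThresholds(area_max=30))
        assert len(kids) == 2
        union = set()
        for k in kids:
            assert k.provenance == "shrink-split"
            assert not union & k.pixel_set()
            union |= k.pixel_set()
        assert union == seg.pixel_set()
        # bridge splits near its midline: each child holds one full square
        areas = sorted(k.area for k in kids)
        assert areas[0] >= 25 and areas[1] <= 28

    def test_segment_that_vanishes_is_returned_unchanged(self):
        m = np.zeros((4, 10), dtype=np.uint8)
        m[1, 1:9] = 1  # 1-px line: first peel removes everything
        seg = connected_components(m).segments[0]
        kids = shrink_boundary(seg, SegmentThresholds(area_max=3))
        assert len(kids) == 1 and kids[0].note == "unsplittable"


class TestExpandMerge:
    def _set(self, segs):
        return SegmentSet(segments=segs, shape=(20, 20))

    def test_merge_conserves_area(self):
        frag = Segment(id=99, rows=[5], cols=[5])
        nb = Segment(id=1, rows=[5, 5, 5], cols=[6, 7, 8])
        t = SegmentThresholds(area_min=2)
        out = expand_merge(frag, self._set([nb]), t)
        assert len(out) == 1
        merged = out.segments[0]
        assert merged.area == 4
        assert merged.provenance == "merged"

    def test_isolated_fragment_deleted(self):
        frag = Segment(id=99, rows=[0], cols=[0])
        nb = Segment(id=1, rows=[10], cols=[10])
        out = expand_merge(frag, self._set([nb]), SegmentThresholds(area_min=2))
        assert len(out) == 1 and out.segments[0].area == 1
        assert out.segments[0].id == 1

    def test_two_siblings_longest_disabled_border_wins(self):
        # fragment row touching two neighbors; neighbor 2 shares the longer
        # border through disabled pixels
        frag = Segment(id=99, rows=[5, 5, 5], cols=[4, 5, 6])
        nb1 = Segment(id=1, rows=[4], cols=[4])
        nb2 = Segment(id=2, rows=[6, 6, 6], cols=[4, 5, 6])
        disabled = {(5, 4), (5, 5), (5, 6)}
        out = expand_merge(
            frag, self._set([nb1, nb2]), SegmentThresholds(), disabled=disabled
        )
        by_id = {s.id: s for s in out}
        assert by_id[2].area == 6          # merged with the 3-px neighbor
        assert by_id[1].area == 1
        # brute-force border count confirms the choice
        def border(a, b):
            n = 0
            for (r1, c1) in a:
                for (r2, c2) in b:
                    if max(abs(r1 - r2), abs(c1 - c2)) == 1 and (
                        (r1, c1) in disabled or (r2, c2) in disabled
                    ):
                        n += 1
            return n
        f = frag.pixel_set()
        assert border(f, nb2.pixel_set()) > border(f, nb1.pixel_set())


class TestSegmentPipeline:
    def test_disjoint_scene_counts_exactly(self, small_scene, permissive_thresholds):
        img, truth = small_scene
        mask = (truth.label_image() > 0).astype(np.uint8)
        segs = segment_pipeline(mask, permissive_thresholds)
        assert len(segs) == truth.count

    def test_all_zero_mask_gives_empty_set(self):
        out = segment_pipeline(np.zeros((10, 10), dtype=np.uint8), SegmentThresholds())
        assert len(out) == 0

    def test_easy_input_equals_prune_of_components(self):
        rng = np.random.default_rng(0)
        m = (rng.random((40, 40)) < 0.3).astype(np.uint8)
        t = SegmentThresholds(area_min=3)
        a = segment_pipeline(m, t)
        b = prune_lower(connected_components(m), t)
        assert {frozenset(s.pixel_set()) for s in a} == {
            frozenset(s.pixel_set()) for s in b
        }

    def test_touching_pair_is_split_with_thresholds(self):
        # 5 disjoint disks + one fused pair; upper bound between single and pair
        singles = [(10, 10), (10, 30), (10, 50), (30, 10), (30, 30)]
        m = disk_mask((60, 60), singles, 6)
        m |= disk_mask((60, 60), [(45, 40), (45, 51)], 6)
        one = float(disk_mask((30, 30), [(15, 15)], 6).sum())
        t = SegmentThresholds(area_min=10, area_max=1.5 * one)
        segs = segment_pipeline(m.astype(np.uint8), t)
        assert len(segs) == 7

    def test_raising_area_min_never_increases_count(self):
        rng = np.random.default_rng(5)
        m = (rng.random((50, 50)) < 0.35).astype(np.uint8)
        counts = [
            len(segment_pipeline(m, SegmentThresholds(area_min=amin)))
            for amin in (0, 2, 4, 8, 16)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        m = (rng.random((50, 50)) < 0.4).astype(np.uint8)
        t = SegmentThresholds(area_min=2, area_max=60)
        a = segment_pipeline(m, t)
        b = segment_pipeline(m, t)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.rows, y.rows)
            np.testing.assert_array_equal(x.cols, y.cols)

    def test_retained_segments_respect_lower_bounds_and_flag_unsplittable(self):
        m = disk_mask((40, 60), [(20, 23), (20, 37)], 8) | disk_mask(
            (40, 60), [(5, 55)], 2
        )
        # absurdly low upper bound: nothing can be split small enough
        t = SegmentThresholds(area_min=5, area_max=20)
        segs = segment_pipeline(m.astype(np.uint8), t)
        for s in segs:
            assert s.area >= 5
            if s.area > 20:
                assert s.note == "unsplittable"

    def test_pixel_conservation_of_splitting(self):
        m = disk_mask((40, 60), [(20, 23), (20, 37)], 8)
        one = math.pi * 64
        t = SegmentThresholds(area_max=1.5 * one)
        segs = segment_pipeline(m.astype(np.uint8), t)
        assert sum(s.area for s in segs) == int(m.sum())
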