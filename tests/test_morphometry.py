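import math

import numpy as np
import pytest

from gridfree.morphometry import (
    apply_scale,
    boundary_pixels,
    make_scale,
    measure_length_width,
)
from gridfree.segmentation import Segment, connected_components


def segment_from_mask(mask):
    return connected_components(mask.astype(np.uint8)).segments[0]


def disk_segment(radius, pad=3):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius + pad
    return segment_from_mask((yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2)


def brute_force_length_width(pts):
    """All-pairs oracle for the longest boundary chord and the extent of
    boundary projections perpendicular to it (first raster pair on ties)."""
    pts = np.asarray(pts, dtype=float)
    best_d2, best = -1, None
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d2 = np.sum((pts[j] - pts[i]) ** 2)
            if d2 > best_d2:
                best_d2, best = d2, (pts[i], pts[j])
    p, q = best
    length = math.sqrt(best_d2)
    axis = (q - p) / length
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    return length, float(proj.max() - proj.min())


class TestBoundaryPixels:
    def test_single_pixel_is_its_own_boundary(self):
        seg = Segment(id=1, rows=[3], cols=[4])
        np.testing.assert_array_equal(boundary_pixels(seg), [[3, 4]])

    def test_3x3_square_boundary_is_the_8_border_pixels(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:4, 1:4] = 1
        pts = {tuple(p) for p in boundary_pixels(segment_from_mask(m))}
        expected = {(i, j) for i in (1, 2, 3) for j in (1, 2, 3)} - {(2, 2)}
        assert pts == expected

    def test_matches_per_pixel_neighbor_oracle(self):
        rng = np.random.default_rng(4)
        m = np.zeros((20, 20), dtype=np.uint8)
        m[4:16, 4:16] = (rng.random((12, 12)) < 0.7).astype(np.uint8)
        for seg in connected_components(m):
            got = {tuple(p) for p in boundary_pixels(seg)}
            pix = seg.pixel_set()
            expected = set()
            for (r, c) in pix:
                nbhd = {
                    (r + dr, c + dc)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0)
                }
                if nbhd - pix:
                    expected.add((r, c))
            assert got == expected


class TestMeasureLengthWidth:
    def test_horizontal_run_of_five(self):
        seg = Segment(id=1, rows=[2] * 5, cols=list(range(1, 6)))
        m = measure_length_width(seg)
        assert m.length_px == pytest.approx(4.0)
        assert m.width_px == pytest.approx(0.0)
        assert m.area_px == 5

    def test_3x5_rectangle_matches_brute_force(self):
        mask = np.zeros((7, 9), dtype=np.uint8)
        mask[2:5, 2:7] = 1
        seg = segment_from_mask(mask)
        m = measure_length_width(seg)
        assert m.length_px == pytest.approx(math.sqrt(20))
        ell, wid = brute_force_length_width(boundary_pixels(seg))
        assert m.length_px == pytest.approx(ell)
        assert m.width_px == pytest.approx(wid)

    def test_random_blobs_match_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            m = np.zeros((18, 18), dtype=np.uint8)
            m[3:15, 3:15] = (rng.random((12, 12)) < 0.75).astype(np.uint8)
            segs = connected_components(m)
            for seg in segs.segments[:3]:
                if seg.area < 2:
                    continue
                got = measure_length_width(seg)
                ell, wid = brute_force_length_width(boundary_pixels(seg))
                assert got.length_px == pytest.approx(ell)
                assert got.width_px == pytest.approx(wid)

    def test_digital_disk_dimensions(self):
        m = measure_length_width(disk_segment(10))
        assert m.length_px == pytest.approx(20.0, abs=1.0)
        assert abs(m.length_px - m.width_px) <= 1.0

    def test_width_never_exceeds_length_nor_bbox_diagonal(self):
        rng = np.random.default_rng(8)
        m = np.zeros((25, 25), dtype=np.uint8)
        m[5:20, 5:20] = (rng.random((15, 15)) < 0.6).astype(np.uint8)
        for seg in connected_components(m):
            got = measure_length_width(seg)
            assert got.width_px <= got.length_px + 1e-9
            assert got.length_px <= seg.diagonal + 1.0

    def test_rotation_by_90_degrees_changes_little(self):
        yy, xx = np.mgrid[0:40, 0:40]
        blob = ((yy - 20) / 12.0) ** 2 + ((xx - 20) / 6.0) ** 2 <= 1.0
        a = measure_length_width(segment_from_mask(blob))
        b = measure_length_width(segment_from_mask(blob.T))
        assert abs(a.length_px - b.length_px) < 1.0
        assert abs(a.width_px - b.width_px) < 1.0


class TestScaling:
    def test_make_scale_arithmetic(self):
        seg = Segment(id=1, rows=np.zeros(100, dtype=int), cols=np.arange(100))
        scale = make_scale(seg, 50.0)
        assert scale.area_ratio == pytest.approx(0.5)
        assert scale.linear_ratio == pytest.approx(math.sqrt(0.5))
        assert scale.area_ratio * scale.ref_area_px == pytest.approx(
            scale.ref_area_mm2, rel=1e-9
        )

    def test_unit_reference(self):
        seg = Segment(id=1, rows=[0], cols=[0])
        scale = make_scale(seg, 1.0)
        assert scale.area_ratio == 1.0 and scale.linear_ratio == 1.0

    def test_double_resolution_quarters_area_ratio(self):
        small = disk_segment(10)
        big = disk_segment(20)
        s1 = make_scale(small, 100.0)
        s2 = make_scale(big, 100.0)
        assert s2.area_ratio == pytest.approx(s1.area_ratio / 4, rel=0.03)
        assert s2.linear_ratio == pytest.approx(s1.linear_ratio / 2, rel=0.02)

    def test_apply_scale_is_linear(self):
        m = measure_length_width(disk_segment(8))
        s1 = make_scale(disk_segment(10), 100.0)
        s2 = make_scale(disk_segment(10), 200.0)
        out1 = apply_scale(m, s1)
        out2 = apply_scale(m, s2)
        assert out2.area_mm2 == pytest.approx(2 * out1.area_mm2)
        assert out1.length_mm == pytest.approx(m.length_px * s1.linear_ratio)
        assert out1.width_mm == pytest.approx(m.width_px * s1.linear_ratio)

    def test_identity_scale_keeps_lengths(self):
        m = measure_length_width(disk_segment(6))
        seg = disk_segment(6)
        scale = make_scale(seg, float(seg.area))  # 1 mm^2 per px
        out = apply_scale(m, scale)
        assert out.length_mm == pytest.approx(m.length_px)

    def test_invalid_reference_area_rejected(self):
        with pytest.raises(ValueError):
            make_scale(disk_segment(5), 0.0)
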