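"""Length, width and area measurement of segments, with physical scaling.

Length is the longest Euclidean distance between two boundary-pixel centers
of an object; width is the extent of the boundary pixels projected onto the
axis perpendicular to that longest chord.  For convex objects this equals
the longest perpendicular chord; for concave ones it is a deterministic,
well-defined generalization.  Distances are between pixel centers, so a
horizontal run of five pixels has length 4.0.

Physical units come from a reference object of known area: only its total
area matters, not its shape.  The pixel-to-mm^2 area ratio converts areas;
its square root (the unique dimensionally consistent extension) converts
lengths and widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .segmentation import Segment, SegmentSet

__all__ = [
    "Morphometrics",
    "ScaleRef",
    "boundary_pixels",
    "measure_length_width",
    "measure_segments",
    "make_scale",
    "apply_scale",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Morphometrics:
    """Per-segment measurements; mm fields are set once a scale is applied."""

    length_px: float
    width_px: float
    area_px: int
    length_axis: Tuple[float, float]  # unit vector (d_row, d_col)
    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    area_mm2: Optional[float] = None


@dataclass(frozen=True)
class ScaleRef:
    """Pixel-to-physical calibration from one reference object."""

    ref_segment_id: int
    ref_area_px: int
    ref_area_mm2: float
    area_ratio: float    # mm^2 per pixel
    linear_ratio: float  # mm per pixel

    def __post_init__(self) -> None:
        if min(self.ref_area_px, self.ref_area_mm2,
               self.area_ratio, self.linear_ratio) <= 0:
            raise ValueError("scale reference quantities must all be positive")


def boundary_pixels(segment: Segment) -> np.ndarray:
    """Segment pixels with at least one of their 8 neighbors outside it.

    Returned as an ``(n, 2)`` array of (row, col) in raster order.
    """
    mask, origin = segment.local_mask(pad=1)
    interior = ndi.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    rr, cc = np.nonzero(mask & ~interior)
    pts = np.column_stack([rr + origin[0], cc + origin[1]])
    return pts.astype(np.int64)


def _diameter_pair(pts: np.ndarray) -> Tuple[np.ndarray, np.ndarray, int]:
    """Farthest pair of integer points; ties resolved to the first raster pair.

    The diameter endpoints are extreme points, so the search runs over the
    convex hull vertices; squared distances are exact integers, making the
    tie-break deterministic.  Degenerate (collinear) point sets fall back to
    the full pairwise search.
    """
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            cand = pts[np.sort(hull.vertices)]  # ascending index = raster order
        except QhullError:
            cand = pts
    else:
        cand = pts
    best_d2 = -1
    best = (cand[0], cand[0])
    for i in range(len(cand)):
        d = cand[i + 1:] - cand[i]
        if len(d) == 0:
            continue
        d2 = d[:, 0] ** 2 + d[:, 1] ** 2
        j = int(np.argmax(d2))
        if int(d2[j]) > best_d2:
            best_d2 = int(d2[j])
            best = (cand[i], cand[i + 1 + j])
    return best[0], best[1], best_d2


def measure_length_width(segment: Segment) -> Morphometrics:
    """Longest boundary chord (length) and perpendicular extent (width)."""
    pts = boundary_pixels(segment)
    if len(pts) == 1:
        return Morphometrics(length_px=0.0, width_px=0.0, area_px=segment.area,
                             length_axis=(0.0, 0.0))
    p, q, d2 = _diameter_pair(pts)
    length = math.sqrt(d2)
    axis = ((q - p) / length).astype(np.float64)
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    width = float(proj.max() - proj.min())
    return Morphometrics(length_px=length, width_px=width, area_px=segment.area,
                         length_axis=(float(axis[0]), float(axis[1])))


def measure_segments(segments: SegmentSet) -> List[Morphometrics]:
    """Measurements for every segment, in segment order."""
    return [measure_length_width(s) for s in segments]


def make_scale(segment: Segment, ref_area_mm2: float) -> ScaleRef:
    """Calibrate mm-per-pixel ratios from a reference object of known area."""
    if ref_area_mm2 <= 0:
        raise ValueError(f"reference area must be positive, got {ref_area_mm2}")
    area_ratio = ref_area_mm2 / segment.area
    return ScaleRef(
        ref_segment_id=segment.id,
        ref_area_px=segment.area,
        ref_area_mm2=float(ref_area_mm2),
        area_ratio=float(area_ratio),
        linear_ratio=float(math.sqrt(area_ratio)),
    )


def apply_scale(metrics: Morphometrics, scale: ScaleRef) -> Morphometrics:
    """Convert pixel measurements to millimeters with a scale reference."""
    return replace(
        metrics,
        area_mm2=metrics.area_px * scale.area_ratio,
        length_mm=metrics.length_px * scale.linear_ratio,
        width_mm=metrics.width_px * scale.linear_ratio,
    )
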