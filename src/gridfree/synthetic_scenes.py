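"""Ground-truthed synthetic scenes: colored ellipse kernels on a contrasting
background.

The generator emulates photographs of seeds scattered on a plain sheet: dark
elliptical kernels on a light background (or the reverse), per-pixel Gaussian
sensor noise, optional small specks of the kernel color (harvest rubble),
optional tangent kernel pairs at a controlled fraction, and an optional
circular reference object of known physical area.  Every placement and the
rendered pixel ownership of each kernel are recorded, so segmentation and
measurement results can be scored against exact truth.

Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .segmentation import SegmentSet

__all__ = [
    "ReferenceDisk",
    "SceneSpec",
    "EllipseTruth",
    "GroundTruth",
    "MatchReport",
    "generate_scene",
    "score_against_truth",
]


class GenerationError(RuntimeError):
    """Raised when objects cannot be placed at the requested density."""


@dataclass(frozen=True)
class ReferenceDisk:
    """In-scene circular size reference: rendered radius and nominal area."""

    radius_px: float = 40.0
    area_mm2: float = 285.0  # about a US penny


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene.

    ``axis_mean``/``axis_sd`` describe Gaussian semi-axes in pixels (major,
    minor), clipped at 3 px; ``axis_range`` switches to uniform sampling of
    both semi-axes over (low, high).  ``fraction_touching`` is the fraction
    of objects placed in tangent pairs, overlapping by ``touch_overlap``
    pixels along the line of centers so that the rendered pair is
    8-connected.  Colors are 8-bit RGB; ``noise_sd`` is per-pixel,
    per-channel Gaussian noise.
    """

    shape: Tuple[int, int] = (1200, 1200)
    n_objects: int = 200
    axis_mean: Tuple[float, float] = (14.0, 9.0)
    axis_sd: Tuple[float, float] = (1.0, 0.6)
    axis_range: Optional[Tuple[float, float]] = None
    fill_color: Tuple[int, int, int] = (120, 78, 40)
    bg_color: Tuple[int, int, int] = (235, 235, 235)
    noise_sd: float = 8.0
    fraction_touching: float = 0.0
    touch_overlap: float = 1.5
    n_specks: int = 0
    speck_radius: Tuple[float, float] = (1.0, 2.0)
    reference: Optional[ReferenceDisk] = None
    min_separation: float = 3.0
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if not 0.0 <= self.fraction_touching <= 1.0:
            raise ValueError("fraction_touching must be in [0, 1]")
        for col in (self.fill_color, self.bg_color):
            if any(not 0 <= v <= 255 for v in col):
                raise ValueError("colors must be 8-bit (0-255)")


@dataclass
class EllipseTruth:
    """One rendered kernel: analytic parameters plus exact pixel ownership."""

    id: int
    center: Tuple[float, float]       # (row, col)
    semi_axes: Tuple[float, float]    # (a, b), a >= b
    rotation: float                   # radians
    rows: np.ndarray
    cols: np.ndarray
    touching_partner: Optional[int] = None
    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    area_mm2: Optional[float] = None

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    @property
    def length_px(self) -> float:
        return 2.0 * self.semi_axes[0]

    @property
    def width_px(self) -> float:
        return 2.0 * self.semi_axes[1]

    @property
    def area_px_analytic(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass
class GroundTruth:
    """Scene-level truth: objects, optional reference, specks."""

    objects: List[EllipseTruth]
    shape: Tuple[int, int]
    reference_rows: Optional[np.ndarray] = None
    reference_cols: Optional[np.ndarray] = None
    reference_area_mm2: Optional[float] = None
    speck_pixels: int = 0

    @property
    def count(self) -> int:
        return len(self.objects)

    @property
    def reference_area_px(self) -> Optional[int]:
        return None if self.reference_rows is None else int(self.reference_rows.size)

    def linear_ratio(self) -> Optional[float]:
        """mm per pixel implied by the rendered reference object."""
        if self.reference_area_mm2 is None or not self.reference_area_px:
            return None
        return math.sqrt(self.reference_area_mm2 / self.reference_area_px)

    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=np.int32)
        for obj in self.objects:
            lab[obj.rows, obj.cols] = obj.id
        return lab


def _support_radius(a: float, b: float, rotation: float, theta: float) -> float:
    """Distance from center to the ellipse edge along direction ``theta``."""
    t = theta - rotation
    return a * b / math.hypot(b * math.cos(t), a * math.sin(t))


def _sample_axes(spec: SceneSpec, rng: np.random.Generator) -> Tuple[float, float]:
    if spec.axis_range is not None:
        lo, hi = spec.axis_range
        a, b = rng.uniform(lo, hi, size=2)
    else:
        a = rng.normal(spec.axis_mean[0], spec.axis_sd[0])
        b = rng.normal(spec.axis_mean[1], spec.axis_sd[1])
    a, b = max(a, 3.0), max(b, 3.0)
    return (a, b) if a >= b else (b, a)


def _inside_quadratic(
    shape: Tuple[int, int], center: Tuple[float, float],
    axes: Tuple[float, float], rotation: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels whose centers lie inside the ellipse, with normalized radius^2."""
    a, b = axes
    cr, cc = center
    rad = max(a, b) + 1.0
    r0 = max(0, int(math.floor(cr - rad)))
    r1 = min(shape[0] - 1, int(math.ceil(cr + rad)))
    c0 = max(0, int(math.floor(cc - rad)))
    c1 = min(shape[1] - 1, int(math.ceil(cc + rad)))
    rr, cc2 = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    dr = rr - cr
    dc = cc2 - cc
    co, si = math.cos(rotation), math.sin(rotation)
    u = co * dr + si * dc
    v = -si * dr + co * dc
    q = (u / a) ** 2 + (v / b) ** 2
    sel = q <= 1.0
    return rr[sel], cc2[sel], q[sel]


@dataclass
class _Placed:
    center: Tuple[float, float]
    axes: Tuple[float, float]
    rotation: float
    bound_r: float


def _clear_of(placed: Sequence[_Placed], center, bound_r, skip: int = -1) -> bool:
    for i, p in enumerate(placed):
        if i == skip:
            continue
        if math.hypot(center[0] - p.center[0], center[1] - p.center[1]) < bound_r + p.bound_r:
            return False
    return True


def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Render a scene and its exact ground truth.

    Placement uses rejection sampling on bounding circles (guaranteeing at
    least ``min_separation`` pixels between non-touching objects); each
    object gets at most ``max_attempts`` draws before a
    :class:`GenerationError` suggests a larger canvas.  Touching pairs are
    placed tangent along a random direction, overlapping by
    ``touch_overlap`` px; contested pixels belong to the ellipse whose
    normalized radius is smaller (the nearer center).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    n_pairs = int(round(spec.n_objects * spec.fraction_touching / 2.0))
    n_singles = spec.n_objects - 2 * n_pairs

    placed: List[_Placed] = []
    pair_of: Dict[int, int] = {}

    def place_one(axes, pair_anchor: Optional[int] = None) -> _Placed:
        a, b = axes
        bound = a + spec.min_separation
        for _ in range(spec.max_attempts):
            if pair_anchor is None:
                center = (rng.uniform(bound, h - bound), rng.uniform(bound, w - bound))
            else:
                anchor = placed[pair_anchor]
                theta = rng.uniform(0, 2 * math.pi)
                rot = rng.uniform(0, math.pi)
                d = (_support_radius(*anchor.axes, anchor.rotation, theta)
                     + _support_radius(a, b, rot, theta + math.pi)
                     - spec.touch_overlap)
                # displacement (d_row, d_col) = d * (cos theta, sin theta)
                # matches the angle convention of the support radius
                center = (anchor.center[0] + d * math.cos(theta),
                          anchor.center[1] + d * math.sin(theta))
                if not (bound <= center[0] <= h - bound and bound <= center[1] <= w - bound):
                    continue
                if not _clear_of(placed, center, bound, skip=pair_anchor):
                    continue
                return _Placed(center, (a, b), rot, bound)
            if _clear_of(placed, center, bound):
                rot = rng.uniform(0, math.pi)
                return _Placed(center, axes, rot, bound)
        raise GenerationError(
            f"could not place object after {spec.max_attempts} attempts; "
            "the canvas is too small for the requested density"
        )

    for _ in range(n_singles):
        placed.append(place_one(_sample_axes(spec, rng)))
    for _ in range(n_pairs):
        first = place_one(_sample_axes(spec, rng))
        placed.append(first)
        i_first = len(placed) - 1
        second = place_one(_sample_axes(spec, rng), pair_anchor=i_first)
        placed.append(second)
        pair_of[i_first] = i_first + 1
        pair_of[i_first + 1] = i_first

    ref_placed: Optional[_Placed] = None
    if spec.reference is not None:
        r = spec.reference.radius_px
        ref_placed = place_one((r, r))

    # render ownership: nearest normalized center wins on contested pixels
    owner = np.zeros((h, w), dtype=np.int32)
    qmin = np.full((h, w), np.inf, dtype=np.float64)
    for i, p in enumerate(placed):
        rr, cc, q = _inside_quadratic((h, w), p.center, p.axes, p.rotation)
        take = q < qmin[rr, cc]
        owner[rr[take], cc[take]] = i + 1
        qmin[rr[take], cc[take]] = q[take]

    ref_id = len(placed) + 1
    if ref_placed is not None:
        rr, cc, q = _inside_quadratic((h, w), ref_placed.center,
                                      ref_placed.axes, ref_placed.rotation)
        take = q < qmin[rr, cc]
        owner[rr[take], cc[take]] = ref_id
        qmin[rr[take], cc[take]] = q[take]

    # specks: small kernel-colored disks, each below 20% of the smallest object
    speck_pixels = 0
    if spec.n_specks > 0:
        min_area = min(math.pi * p.axes[0] * p.axes[1] for p in placed) if placed else math.inf
        speck_id = ref_id + 1
        for _ in range(spec.n_specks):
            lo, hi = spec.speck_radius
            r = rng.uniform(lo, hi)
            if math.pi * r * r > 0.2 * min_area:
                r = math.sqrt(0.2 * min_area / math.pi)
            for _ in range(spec.max_attempts):
                center = (rng.uniform(r + 1, h - r - 1), rng.uniform(r + 1, w - r - 1))
                if _clear_of(placed + ([ref_placed] if ref_placed else []),
                             center, r + spec.min_separation):
                    break
            else:
                raise GenerationError("could not place speck; canvas too dense")
            rr, cc, q = _inside_quadratic((h, w), center, (r, r), 0.0)
            owner[rr, cc] = speck_id
            speck_pixels += rr.size
            speck_id += 1

    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = np.asarray(spec.bg_color, dtype=np.float64)
    fg = owner > 0
    canvas[fg] = np.asarray(spec.fill_color, dtype=np.float64)
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)

    # collect truth pixel sets from the ownership map (single raster scan,
    # grouped by owner id; stable sort keeps raster order within each object)
    n_obj = len(placed)
    rr_all, cc_all = np.nonzero((owner > 0) & (owner <= n_obj))
    lab_all = owner[rr_all, cc_all]
    order = np.argsort(lab_all, kind="stable")
    rr_all, cc_all, lab_all = rr_all[order], cc_all[order], lab_all[order]
    bounds = np.searchsorted(lab_all, np.arange(1, n_obj + 2))
    objects: List[EllipseTruth] = []
    for i, p in enumerate(placed):
        sl = slice(bounds[i], bounds[i + 1])
        objects.append(EllipseTruth(
            id=i + 1, center=p.center, semi_axes=p.axes, rotation=p.rotation,
            rows=rr_all[sl].astype(np.int32), cols=cc_all[sl].astype(np.int32),
            touching_partner=(pair_of[i] + 1) if i in pair_of else None,
        ))

    truth = GroundTruth(objects=objects, shape=(h, w), speck_pixels=speck_pixels)
    if ref_placed is not None:
        rr, cc = np.nonzero(owner == ref_id)
        truth.reference_rows = rr.astype(np.int32)
        truth.reference_cols = cc.astype(np.int32)
        truth.reference_area_mm2 = spec.reference.area_mm2
        s = truth.linear_ratio()
        for obj in truth.objects:
            obj.length_mm = obj.length_px * s
            obj.width_mm = obj.width_px * s
            obj.area_mm2 = obj.area_px * s * s
    return image, truth


@dataclass
class MatchReport:
    """Greedy best-IoU matching of predicted segments against truth."""

    n_predicted: int
    n_true: int
    matches: List[Tuple[int, int, float]]  # (truth id, segment id, IoU)
    unmatched_truth: List[int]
    unmatched_predicted: List[int]

    @property
    def count_error(self) -> int:
        return self.n_predicted - self.n_true

    def iou_of_truth(self, truth_id: int) -> float:
        for t, _, iou in self.matches:
            if t == truth_id:
                return iou
        return 0.0


def score_against_truth(segments: SegmentSet, truth: GroundTruth) -> MatchReport:
    """Match segments to truth objects greedily by descending IoU."""
    truth_lab = truth.label_image()
    truth_area = {obj.id: obj.area_px for obj in truth.objects}
    pairs: List[Tuple[float, int, int]] = []
    seg_area = {}
    for seg in segments:
        seg_area[seg.id] = seg.area
        hit = truth_lab[seg.rows, seg.cols]
        ids, counts = np.unique(hit[hit > 0], return_counts=True)
        for tid, inter in zip(ids.tolist(), counts.tolist()):
            union = truth_area[tid] + seg.area - inter
            pairs.append((inter / union, tid, seg.id))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t, used_s = set(), set()
    matches = []
    for iou, tid, sid in pairs:
        if tid in used_t or sid in used_s:
            continue
        used_t.add(tid)
        used_s.add(sid)
        matches.append((tid, sid, iou))
    return MatchReport(
        n_predicted=len(segments),
        n_true=truth.count,
        matches=matches,
        unmatched_truth=sorted(set(truth_area) - used_t),
        unmatched_predicted=sorted(set(seg_area) - used_s),
    )
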