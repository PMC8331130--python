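"""Divide-and-combine segmentation of a binary pixels-of-interest mask.

The engine turns a POI mask into candidate objects in five stages:

1. *Connected components* (8-connectivity flood fill) give the initial
   segments, with ids in raster order of each component's first pixel.
2. *Lower-bound pruning* permanently removes specks whose pixel area or
   bounding-box diagonal falls below the user's lower thresholds.
3. Segments above an upper threshold are suspected fusions of several
   touching objects and are *split*.  The primary splitter is a
   marker-controlled watershed on the negated Euclidean distance transform;
   markers are local maxima of the distance map found with a square search
   neighborhood whose area starts at the mean area of correctly segmented
   objects and shrinks by one-half at a time until enough markers appear (or
   the region collapses to a single pixel).
4. When the watershed cannot find two markers (smooth-rimmed fusions have a
   single distance plateau), *boundary shrinkage* iteratively peels the
   8-connected boundary until the remnant separates into pieces; the peeled
   pixels are then re-enabled by geodesic assignment to the nearest piece, so
   children exactly partition the parent.
5. Undersized split fragments are *expansion-merged* into the adjacent
   sibling sharing the longest border (or deleted if isolated).

Areas are POI pixel counts; the "diagonal" of a segment is the diagonal of
its tight bounding box, ``sqrt((height)^2 + (width)^2)`` with height/width
counted in pixels.  Every stage is deterministic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

__all__ = [
    "Segment",
    "SegmentThresholds",
    "SegmentSet",
    "connected_components",
    "prune_lower",
    "estimate_count",
    "watershed_split",
    "peel_once",
    "shrink_boundary",
    "expand_merge",
    "segment_pipeline",
]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentThresholds:
    """User bounds on segment area (pixels) and bounding-box diagonal (pixels)."""

    area_min: float = 0.0
    area_max: float = math.inf
    diag_min: float = 0.0
    diag_max: float = math.inf

    def __post_init__(self) -> None:
        if not (0 <= self.area_min <= self.area_max):
            raise ValueError("need 0 <= area_min <= area_max")
        if not (0 <= self.diag_min <= self.diag_max):
            raise ValueError("need 0 <= diag_min <= diag_max")

    def below_lower(self, seg: "Segment") -> bool:
        return seg.area < self.area_min or seg.diagonal < self.diag_min

    def above_upper(self, seg: "Segment") -> bool:
        return seg.area > self.area_max or seg.diagonal > self.diag_max


@dataclass
class Segment:
    """One 8-connected candidate object: pixel set plus derived geometry."""

    id: int
    rows: np.ndarray        # int32, raster-sorted together with cols
    cols: np.ndarray
    provenance: str = "initial"
    note: Optional[str] = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int32)
        self.cols = np.asarray(self.cols, dtype=np.int32)
        if self.rows.size == 0 or self.rows.size != self.cols.size:
            raise ValueError("segment needs a non-empty, consistent pixel set")

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def bbox(self) -> Tuple[int, int, int, int]:
        return (
            int(self.rows.min()), int(self.cols.min()),
            int(self.rows.max()), int(self.cols.max()),
        )

    @property
    def diagonal(self) -> float:
        rmin, cmin, rmax, cmax = self.bbox
        return math.hypot(rmax - rmin + 1, cmax - cmin + 1)

    @property
    def first_pixel(self) -> Tuple[int, int]:
        return int(self.rows[0]), int(self.cols[0])

    def pixel_set(self) -> Set[Tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def local_mask(self, pad: int = 1) -> Tuple[np.ndarray, Tuple[int, int]]:
        """Boolean mask over the padded bounding box and its (row, col) origin."""
        rmin, cmin, rmax, cmax = self.bbox
        origin = (rmin - pad, cmin - pad)
        mask = np.zeros((rmax - rmin + 1 + 2 * pad, cmax - cmin + 1 + 2 * pad), dtype=bool)
        mask[self.rows - origin[0], self.cols - origin[1]] = True
        return mask, origin


def _segment_from_mask_coords(
    rows: np.ndarray, cols: np.ndarray, origin: Tuple[int, int],
    seg_id: int, provenance: str,
) -> Segment:
    rr = rows + origin[0]
    cc = cols + origin[1]
    order = np.lexsort((cc, rr))
    return Segment(id=seg_id, rows=rr[order], cols=cc[order], provenance=provenance)


@dataclass
class SegmentSet:
    """Disjoint segments over one mask, ids dense 1..n."""

    segments: List[Segment] = field(default_factory=list)
    shape: Tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def get(self, seg_id: int) -> Segment:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise KeyError(f"no segment with id {seg_id}")

    def renumbered(self) -> "SegmentSet":
        """Dense ids 1..n in raster order of each segment's first pixel."""
        segs = sorted(self.segments, key=lambda s: s.first_pixel)
        segs = [replace(s, id=i + 1) for i, s in enumerate(segs)]
        return SegmentSet(segments=segs, shape=self.shape)

    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=np.int32)
        for seg in self.segments:
            lab[seg.rows, seg.cols] = seg.id
        return lab


def connected_components(mask: np.ndarray) -> SegmentSet:
    """8-connected flood-fill components of a binary mask.

    Ids are assigned 1..n in raster order of each component's first
    (topmost-then-leftmost) pixel, matching a breadth-first scan of the grid.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D binary mask")
    lab, n = ndi.label(mask != 0, structure=_STRUCT8)
    if n == 0:
        return SegmentSet(segments=[], shape=mask.shape)
    rr, cc = np.nonzero(lab)               # raster order
    lv = lab[rr, cc]
    order = np.argsort(lv, kind="stable")  # stable: raster order kept per label
    rr, cc, lv = rr[order], cc[order], lv[order]
    bounds = np.searchsorted(lv, np.arange(1, n + 2))
    segments = []
    for i in range(n):
        sl = slice(bounds[i], bounds[i + 1])
        segments.append(Segment(id=i + 1, rows=rr[sl].astype(np.int32),
                                cols=cc[sl].astype(np.int32), provenance="initial"))
    return SegmentSet(segments=segments, shape=mask.shape)


def prune_lower(segments: SegmentSet, t: SegmentThresholds) -> SegmentSet:
    """Permanently drop segments below the lower area or diagonal bound."""
    kept = [s for s in segments if not t.below_lower(s)]
    removed = len(segments) - len(kept)
    if removed:
        logger.info("prune_lower removed %d segment(s) below lower bounds", removed)
    return SegmentSet(segments=kept, shape=segments.shape).renumbered()


def estimate_count(region_area: int, mean_area: float) -> int:
    """Estimated number of objects fused into a region: area quotient, rounded.

    Rounds half-up to the nearest integer and never returns less than 2 — a
    region only reaches the splitter when it is suspected to hold multiple
    objects.
    """
    if mean_area <= 0:
        raise ValueError(f"mean_area must be positive, got {mean_area}")
    return max(2, int(math.floor(region_area / mean_area + 0.5)))


def _find_markers(
    edt: np.ndarray, mask: np.ndarray, side: int
) -> Tuple[np.ndarray, int]:
    """Plateau-merged local maxima of the distance map in a side x side window.

    Returns a marker label image (one id per plateau, placed on the plateau
    pixel closest to its centroid) and the marker count.
    """
    if side <= 1:
        peaks = mask.copy()
    else:
        mx = ndi.maximum_filter(edt, size=side, mode="constant", cval=0.0)
        peaks = mask & (edt >= mx)
    plat, n = ndi.label(peaks, structure=_STRUCT8)
    markers = np.zeros(edt.shape, dtype=np.int32)
    for m in range(1, n + 1):
        pr, pc = np.nonzero(plat == m)
        cen_r, cen_c = pr.mean(), pc.mean()
        j = int(np.argmin((pr - cen_r) ** 2 + (pc - cen_c) ** 2))
        markers[pr[j], pc[j]] = m
    return markers, n


def _peak_prominences(edt: np.ndarray, mask: np.ndarray):
    """Distance-map peaks with their topographic prominence (persistence).

    Pixels are flooded in order of decreasing distance value; every maximum
    founds a component, and when a component meets a deeper one at level v
    its peak dies with prominence ``depth - v``.  The globally deepest peak
    gets its full depth as prominence.  Returns a list of
    ``(prominence, depth, row, col)`` tuples sorted by decreasing prominence
    (ties: deeper first, then raster order), one per peak.
    """
    rr, cc = np.nonzero(mask)
    vals = edt[rr, cc]
    order = np.lexsort((cc, rr, -vals))  # value desc, raster among equals
    h, w = edt.shape
    index = np.full(edt.shape, -1, dtype=np.int64)
    parent: List[int] = []
    comp_peak: List[int] = []           # founder pixel index per component
    founders: List[Tuple[int, int]] = []
    founder_depth: List[float] = []
    prominence: Dict[int, float] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in order:
        r, c = int(rr[j]), int(cc[j])
        v = float(vals[j])
        neigh = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and index[r2, c2] >= 0:
                    neigh.add(find(int(index[r2, c2])))
        if not neigh:
            k = len(parent)
            parent.append(k)
            comp_peak.append(k)
            founders.append((r, c))
            founder_depth.append(v)
            index[r, c] = k
            continue
        # attach to the deepest neighboring component; other components die
        best = max(neigh, key=lambda k: (founder_depth[comp_peak[k]],
                                         -founders[comp_peak[k]][0],
                                         -founders[comp_peak[k]][1]))
        index[r, c] = best
        for k in neigh:
            if k == best:
                continue
            dead = comp_peak[k]
            prominence[dead] = founder_depth[dead] - v
            parent[k] = best
    for k in range(len(parent)):
        if find(k) == k:
            prominence[comp_peak[k]] = founder_depth[comp_peak[k]]
    peaks = [(prominence[f], founder_depth[f], founders[f][0], founders[f][1])
             for f in prominence]
    peaks.sort(key=lambda p: (-p[0], -p[1], p[2], p[3]))
    return peaks


def watershed_split(segment: Segment, mean_area: float, target: int) -> List[Segment]:
    """Split a fused segment with a dynamic-search-region watershed.

    How many markers exist is decided by the dynamic search: local maxima of
    the Euclidean distance transform are counted in a square neighborhood
    whose area starts at ``mean_area`` (so the first shrink removes one-half
    of the mean area) and halves while fewer than ``target`` maxima are
    found, stopping when the region reaches one pixel.  If the search never
    sees two maxima the segment is returned unchanged with a note.

    Which pixels serve as the ``target`` markers is decided by topographic
    prominence: distance-map peaks are ranked by their persistence (depth
    above the saddle toward any deeper peak), so genuine object centers beat
    the sub-pixel ridge wobble of the discrete distance transform.  The
    negated distance map is then flooded from those markers.
    """
    if target < 2:
        raise ValueError(f"split target must be >= 2, got {target}")
    if mean_area <= 0:
        raise ValueError(f"mean_area must be positive, got {mean_area}")
    mask, origin = segment.local_mask(pad=1)
    edt = ndi.distance_transform_edt(mask)
    region = float(mean_area)
    while True:
        side = max(1, int(math.floor(math.sqrt(max(region, 1.0)) + 0.5)))
        _, n_markers = _find_markers(edt, mask, side)
        if n_markers >= target or region <= 1:
            break
        region /= 2.0
        if region < 1:
            region = 1.0
    if n_markers < 2:
        logger.info("segment %d: marker search found %d marker(s); left unsplit",
                    segment.id, n_markers)
        return [replace(segment, note="unsplittable")]
    n_use = min(target, n_markers)
    peaks = _peak_prominences(edt, mask)[:n_use]
    markers = np.zeros(edt.shape, dtype=np.int32)
    for new_id, (_, _, r, c) in enumerate(
            sorted(peaks, key=lambda p: (p[2], p[3])), start=1):
        markers[r, c] = new_id
    basins = watershed(-edt, markers, mask=mask, connectivity=2)
    children: List[Segment] = []
    for m in range(1, len(peaks) + 1):
        child_mask = basins == m
        if not child_mask.any():
            continue
        comp, n_comp = ndi.label(child_mask, structure=_STRUCT8)
        for c in range(1, n_comp + 1):
            rr, cc = np.nonzero(comp == c)
            children.append(_segment_from_mask_coords(
                rr, cc, origin, seg_id=0, provenance="watershed-split"))
    assert sum(c.area for c in children) == segment.area, "watershed lost pixels"
    if len(children) == 1:
        return [replace(segment, note="unsplittable")]
    return children


def _geodesic_assign(seed_labels: np.ndarray, disabled: np.ndarray) -> np.ndarray:
    """Grow seed labels into the disabled set, one 8-connected step at a time.

    Pixels equidistant (in geodesic steps) from several seeds take the lowest
    label, which keeps the assignment deterministic.
    """
    lab = seed_labels.astype(np.int64)
    big = np.iinfo(np.int64).max
    todo = disabled & (lab == 0)
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    while todo.any():
        cur = np.where(lab > 0, lab, big)
        nb_min = np.full(lab.shape, big, dtype=np.int64)
        for dr, dc in shifts:
            shifted = np.full(lab.shape, big, dtype=np.int64)
            src = cur[max(0, -dr):cur.shape[0] - max(0, dr),
                      max(0, -dc):cur.shape[1] - max(0, dc)]
            shifted[max(0, dr):lab.shape[0] - max(0, -dr),
                    max(0, dc):lab.shape[1] - max(0, -dc)] = src
            np.minimum(nb_min, shifted, out=nb_min)
        newly = todo & (nb_min < big)
        if not newly.any():
            break  # disabled pixels unreachable from any seed (cannot happen
                   # for peeled boundaries of a connected segment)
        lab[newly] = nb_min[newly]
        todo &= ~newly
    return lab


def peel_once(mask: np.ndarray) -> np.ndarray:
    """One boundary-shrinkage step: drop pixels with any background 8-neighbor."""
    m = np.asarray(mask).astype(bool)
    return ndi.binary_erosion(m, structure=_STRUCT8, border_value=0)


def _shrink_with_info(
    segment: Segment, t: SegmentThresholds
) -> Optional[Tuple[List[Segment], np.ndarray, np.ndarray, Tuple[int, int]]]:
    """Boundary-shrinkage core; returns (children, disabled_mask, seed_labels, origin).

    ``None`` means shrinkage could not improve the segment (the remnant
    vanished, or reached the upper bounds while still in one piece, in which
    case re-enabling would simply restore the parent).
    """
    mask, origin = segment.local_mask(pad=1)
    cur = mask.copy()
    while True:
        interior = ndi.binary_erosion(cur, structure=_STRUCT8, border_value=0)
        if not interior.any():
            return None
        lab, n = ndi.label(interior, structure=_STRUCT8)
        cur = interior
        if n >= 2:
            break
        # single remnant component: check the upper bounds on it
        rr, cc = np.nonzero(cur)
        diag = math.hypot(rr.max() - rr.min() + 1, cc.max() - cc.min() + 1)
        if rr.size <= t.area_max and diag <= t.diag_max:
            return None
    disabled = mask & ~cur
    assigned = _geodesic_assign(lab, disabled)
    children: List[Segment] = []
    for m in range(1, n + 1):
        rr, cc = np.nonzero(assigned == m)
        children.append(_segment_from_mask_coords(
            rr, cc, origin, seg_id=0, provenance="shrink-split"))
    assert sum(c.area for c in children) == segment.area, "shrinkage lost pixels"
    return children, disabled, lab, origin


def shrink_boundary(segment: Segment, t: SegmentThresholds) -> List[Segment]:
    """Split a dented fused segment by iterative boundary peeling.

    The 8-connected boundary (pixels with at least one background neighbor)
    is peeled layer by layer until the remnant either separates into two or
    more components or satisfies the upper bounds.  Peeled pixels are then
    re-enabled by geodesic assignment to the nearest remnant component, so
    the children exactly partition the parent's pixels.  If peeling cannot
    separate the segment it is returned unchanged with a note.
    """
    result = _shrink_with_info(segment, t)
    if result is None:
        logger.info("segment %d: boundary shrinkage could not split; left unsplit",
                    segment.id)
        return [replace(segment, note="unsplittable")]
    return result[0]


def _border_count(
    fragment: Segment, neighbor: Segment, disabled: Optional[Set[Tuple[int, int]]]
) -> int:
    """Number of 8-adjacent (fragment pixel, neighbor pixel) pairs.

    When ``disabled`` is given, only pairs with at least one endpoint in the
    disabled set count — the border must run across pixels that were
    disabled during shrinkage.
    """
    frag = fragment.pixel_set()
    count = 0
    for (r, c) in neighbor.pixel_set():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                p = (r + dr, c + dc)
                if p in frag:
                    if disabled is None or p in disabled or (r, c) in disabled:
                        count += 1
    return count


def expand_merge(
    fragment: Segment,
    neighbors: SegmentSet,
    t: SegmentThresholds,
    disabled: Optional[Set[Tuple[int, int]]] = None,
) -> SegmentSet:
    """Merge an undersized split fragment into its best neighbor, or delete it.

    The fragment expands across disabled pixels toward the adjacent segment
    sharing the longest disabled-pixel border.  If the union satisfies the
    lower bounds it replaces that neighbor; if no neighbor shares a border
    (or the union still misses the lower bounds) the fragment is deleted.
    """
    best_id, best_count = None, 0
    for nb in neighbors:
        cnt = _border_count(fragment, nb, disabled)
        if cnt > best_count or (cnt == best_count and cnt > 0
                                and (best_id is None or nb.id < best_id)):
            best_id, best_count = nb.id, cnt
    if best_id is None or best_count == 0:
        logger.info("fragment at %s has no disabled neighbor; deleted",
                    fragment.first_pixel)
        return SegmentSet(segments=list(neighbors), shape=neighbors.shape)
    nb = neighbors.get(best_id)
    rows = np.concatenate([fragment.rows, nb.rows])
    cols = np.concatenate([fragment.cols, nb.cols])
    order = np.lexsort((cols, rows))
    merged = Segment(id=nb.id, rows=rows[order], cols=cols[order], provenance="merged")
    if t.below_lower(merged):
        logger.info("fragment at %s: merged union still below lower bounds; deleted",
                    fragment.first_pixel)
        return SegmentSet(segments=list(neighbors), shape=neighbors.shape)
    segs = [merged if s.id == best_id else s for s in neighbors]
    return SegmentSet(segments=segs, shape=neighbors.shape)


def _mean_reference_area(segments: SegmentSet, t: SegmentThresholds) -> float:
    in_bounds = [s for s in segments if not t.below_lower(s) and not t.above_upper(s)]
    if in_bounds:
        return float(np.mean([s.area for s in in_bounds]))
    warnings.warn("no segment lies within the thresholds; using the mean of all")
    return float(np.mean([s.area for s in segments]))


def segment_pipeline(mask: np.ndarray, t: SegmentThresholds) -> SegmentSet:
    """Full divide-and-combine pass over a POI mask.

    Components below the lower bounds are removed permanently.  Each segment
    above an upper bound is split by the dynamic-search-region watershed
    (with the object count estimated from the mean in-bounds area), falling
    back to boundary shrinkage when the watershed cannot separate it;
    oversized children re-enter the queue.  Undersized fragments produced by
    a split are expansion-merged into their largest-border sibling or
    deleted.  Remaining ids are renumbered densely in raster order.
    """
    initial = connected_components(mask)
    if len(initial) == 0:
        return initial
    segs = prune_lower(initial, t)
    if len(segs) == 0:
        return segs
    mean_area = _mean_reference_area(segs, t)

    final: List[Segment] = []
    queue: List[Segment] = []
    for s in segs:
        (queue if t.above_upper(s) else final).append(s)

    while queue:
        seg = queue.pop(0)
        target = estimate_count(seg.area, mean_area)
        children = watershed_split(seg, mean_area, target)
        if len(children) == 1 and children[0].area == seg.area:
            children = shrink_boundary(seg, t)
        if len(children) == 1 and children[0].area == seg.area:
            logger.info("segment at %s is unsplittable (area %d, diagonal %.1f)",
                        seg.first_pixel, seg.area, seg.diagonal)
            final.append(children[0])
            continue
        # combine stage: merge or delete undersized fragments among siblings
        ok = [c for c in children if not t.below_lower(c)]
        under = [c for c in children if t.below_lower(c)]
        sib = SegmentSet(
            segments=[replace(c, id=i + 1) for i, c in enumerate(ok)],
            shape=initial.shape,
        )
        for frag in under:
            sib = expand_merge(frag, sib, t)
        for c in sib:
            if t.above_upper(c) and c.area < seg.area:
                queue.append(c)
            elif t.above_upper(c):
                final.append(replace(c, note="unsplittable"))
            else:
                final.append(c)

    result = SegmentSet(segments=final, shape=initial.shape).renumbered()
    kept = [s for s in result if not t.below_lower(s)]
    if len(kept) != len(result):
        result = SegmentSet(segments=kept, shape=initial.shape).renumbered()
    return result
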