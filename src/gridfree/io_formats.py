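"""Raster input, result tables, overlays, plots and the parameter file.

Input images are standard 8-bit RGB rasters (PNG/JPEG/TIFF).  An alpha
channel is dropped, 16-bit images are rescaled to 0-255 and grayscale images
are replicated to three identical channels with a warning.

Run parameters round-trip through a JSON file so that a single-image run can
be replayed exactly and a batch run can apply one parameter set to a whole
directory.  Outputs are a measurement CSV (one row per segment), an overlay
PNG with red bounding boxes and id labels, a 16-bit label-mask PNG
(0 = background, segment id elsewhere), and an area-versus-diagonal scatter
PNG with the threshold bars drawn in (red verticals for area, blue
horizontals for diagonal).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw, UnidentifiedImageError

from .decomposition import snap_weight
from .morphometry import Morphometrics, ScaleRef
from .pixel_clustering import EllipseRoi, K_MAX, K_MIN
from .segmentation import SegmentSet, SegmentThresholds

__all__ = [
    "ParameterSet",
    "load_rgb_image",
    "save_rgb_image",
    "write_measurements",
    "write_parameter_file",
    "read_parameter_file",
    "save_overlay",
    "save_label_mask",
    "save_scatter",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def load_rgb_image(path: PathLike) -> np.ndarray:
    """Load a raster image as an ``(h, w, 3)`` uint8 RGB array."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"image file does not exist: {path}")
    try:
        with Image.open(path) as img:
            img.load()
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"image {path} has zero size")
    if arr.ndim == 2:
        if arr.dtype != np.uint8:  # 16-bit (or wider) grayscale
            arr = _rescale_to_uint8(arr)
        logger.warning("grayscale input %s replicated to 3 identical channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3:
        if arr.shape[2] >= 4:
            arr = arr[:, :, :3]
        elif arr.shape[2] != 3:
            raise ValueError(f"image {path} has unsupported channel count {arr.shape[2]}")
        if arr.dtype != np.uint8:
            arr = _rescale_to_uint8(arr)
    else:
        raise ValueError(f"image {path} has unsupported dimensionality {arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image {path} has zero height or width")
    return np.ascontiguousarray(arr.astype(np.uint8))


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    info_max = np.iinfo(arr.dtype).max if np.issubdtype(arr.dtype, np.integer) else arr.max()
    if info_max <= 0:
        return arr.astype(np.uint8)
    return np.floor(arr.astype(np.float64) / info_max * 255.0 + 0.5).astype(np.uint8)


def save_rgb_image(image: np.ndarray, path: PathLike) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(Path(path))


@dataclass
class ParameterSet:
    """Everything needed to replay a run on a comparable image.

    ``selected_index_pc`` is the 1-based index-block component shown and
    clustered; ``rgb_pc_choice`` picks RGB PC1 or PC2 for blending;
    ``rgb_weight`` is the RGB share of the blend on a 0.02 grid (0 means the
    pure index component).  ``selected_clusters`` are the 0-based cluster
    ids that define the POI.
    """

    selected_index_pc: int = 1
    rgb_pc_choice: int = 1
    rgb_weight: float = 0.0
    k: int = 3
    selected_clusters: Tuple[int, ...] = ()
    thresholds: SegmentThresholds = field(default_factory=SegmentThresholds)
    excluded_segment_ids: Tuple[int, ...] = ()
    roi: Optional[EllipseRoi] = None

    def __post_init__(self) -> None:
        if not 1 <= self.selected_index_pc <= 12:
            raise ValueError(
                f"selected_index_pc must be in 1..12, got {self.selected_index_pc}"
            )
        if self.rgb_pc_choice not in (1, 2):
            raise ValueError(f"rgb_pc_choice must be 1 or 2, got {self.rgb_pc_choice}")
        if not K_MIN <= self.k <= K_MAX:
            raise ValueError(f"k must be in {K_MIN}..{K_MAX}, got {self.k}")
        self.rgb_weight = snap_weight(float(self.rgb_weight))
        self.selected_clusters = tuple(sorted(int(c) for c in self.selected_clusters))
        if any(not 0 <= c < self.k for c in self.selected_clusters):
            raise ValueError(
                f"selected_clusters {self.selected_clusters} outside 0..{self.k - 1}"
            )
        self.excluded_segment_ids = tuple(sorted(int(i) for i in self.excluded_segment_ids))


_REQUIRED_KEYS = (
    "selected_index_pc", "rgb_pc_choice", "rgb_weight", "k",
    "selected_clusters", "thresholds", "excluded_segment_ids",
)


def write_parameter_file(params: ParameterSet, path: PathLike) -> None:
    """Serialize a :class:`ParameterSet` to JSON (the batch 'pilot' file)."""
    t = params.thresholds
    doc = {
        "selected_index_pc": params.selected_index_pc,
        "rgb_pc_choice": params.rgb_pc_choice,
        "rgb_weight": params.rgb_weight,
        "k": params.k,
        "selected_clusters": list(params.selected_clusters),
        "thresholds": {
            "area_min": t.area_min,
            "area_max": "inf" if math.isinf(t.area_max) else t.area_max,
            "diag_min": t.diag_min,
            "diag_max": "inf" if math.isinf(t.diag_max) else t.diag_max,
        },
        "excluded_segment_ids": list(params.excluded_segment_ids),
        "roi": None if params.roi is None else {
            "center": list(params.roi.center),
            "semi_axes": list(params.roi.semi_axes),
            "rotation": params.roi.rotation,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_parameter_file(path: PathLike) -> ParameterSet:
    """Parse and validate a parameter JSON file, naming any offending key."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"parameter file {path} is not valid JSON: {exc}") from exc
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise ValueError(f"parameter file {path} is missing required key {key!r}")
    tdoc = doc["thresholds"]
    for key in ("area_min", "area_max", "diag_min", "diag_max"):
        if key not in tdoc:
            raise ValueError(f"parameter file {path}: thresholds missing key {key!r}")

    def _num(v):
        return math.inf if v == "inf" else float(v)

    try:
        thresholds = SegmentThresholds(
            area_min=_num(tdoc["area_min"]), area_max=_num(tdoc["area_max"]),
            diag_min=_num(tdoc["diag_min"]), diag_max=_num(tdoc["diag_max"]),
        )
    except ValueError as exc:
        raise ValueError(f"parameter file {path}: invalid thresholds: {exc}") from exc
    roi = None
    if doc.get("roi") is not None:
        rdoc = doc["roi"]
        roi = EllipseRoi(center=tuple(rdoc["center"]),
                         semi_axes=tuple(rdoc["semi_axes"]),
                         rotation=float(rdoc.get("rotation", 0.0)))
    try:
        return ParameterSet(
            selected_index_pc=int(doc["selected_index_pc"]),
            rgb_pc_choice=int(doc["rgb_pc_choice"]),
            rgb_weight=float(doc["rgb_weight"]),
            k=int(doc["k"]),
            selected_clusters=tuple(doc["selected_clusters"]),
            thresholds=thresholds,
            excluded_segment_ids=tuple(doc["excluded_segment_ids"]),
            roi=roi,
        )
    except ValueError as exc:
        raise ValueError(f"parameter file {path}: {exc}") from exc


MEASUREMENT_COLUMNS = ("id", "area_px", "diagonal_px", "length_px", "width_px")
MM_COLUMNS = ("area_mm2", "length_mm", "width_mm")


def write_measurements(
    segments: SegmentSet,
    metrics: Sequence[Morphometrics],
    path: PathLike,
    scale: Optional[ScaleRef] = None,
) -> pd.DataFrame:
    """One CSV row per segment in id order; mm columns only with a scale."""
    if len(metrics) != len(segments):
        raise ValueError("need exactly one Morphometrics per segment")
    rows = []
    for seg, m in sorted(zip(segments, metrics), key=lambda p: p[0].id):
        row = {
            "id": seg.id,
            "area_px": seg.area,
            "diagonal_px": seg.diagonal,
            "length_px": m.length_px,
            "width_px": m.width_px,
        }
        if scale is not None:
            row["area_mm2"] = seg.area * scale.area_ratio
            row["length_mm"] = m.length_px * scale.linear_ratio
            row["width_mm"] = m.width_px * scale.linear_ratio
        rows.append(row)
    columns = list(MEASUREMENT_COLUMNS) + (list(MM_COLUMNS) if scale is not None else [])
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(Path(path), index=False)
    return frame


def save_overlay(
    image: np.ndarray,
    segments: SegmentSet,
    path: PathLike,
    excluded: Sequence[int] = (),
) -> None:
    """Raw image with red bounding boxes and id labels; excluded ids omitted."""
    img = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB")
    draw = ImageDraw.Draw(img)
    excluded = set(excluded)
    h, w = image.shape[:2]
    for seg in segments:
        if seg.id in excluded:
            continue
        rmin, cmin, rmax, cmax = seg.bbox
        if rmax >= h or cmax >= w:
            raise ValueError(f"segment {seg.id} lies outside the image bounds")
        draw.rectangle([cmin, rmin, cmax, rmax], outline=(255, 0, 0))
        draw.text((cmin, max(0, rmin - 10)), str(seg.id), fill=(255, 0, 0))
    img.save(Path(path))
    logger.info("overlay with %d segment box(es) written to %s",
                len(segments) - len(excluded & {s.id for s in segments}), path)


def save_label_mask(segments: SegmentSet, path: PathLike) -> None:
    """16-bit label-mask PNG: 0 background, segment id elsewhere."""
    lab = segments.label_image()
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many segments for a 16-bit label mask")
    Image.fromarray(lab.astype(np.uint16)).save(Path(path))


def save_scatter(segments: SegmentSet, t: SegmentThresholds, path: PathLike) -> None:
    """Area-versus-diagonal scatter with the four threshold bars drawn in."""
    from matplotlib.figure import Figure
    from matplotlib.backends.backend_agg import FigureCanvasAgg

    fig = Figure(figsize=(6, 4.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    areas = [s.area for s in segments]
    diags = [s.diagonal for s in segments]
    ax.scatter(areas, diags, s=12, c="black", alpha=0.7)
    for x in (t.area_min, t.area_max):
        if math.isfinite(x):
            ax.axvline(x, color="red")
    for y in (t.diag_min, t.diag_max):
        if math.isfinite(y):
            ax.axhline(y, color="blue")
    ax.set_xlabel("segment area (pixels)")
    ax.set_ylabel("segment diagonal (pixels)")
    ax.set_title(f"{len(segments)} segments")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=110)
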