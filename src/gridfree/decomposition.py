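"""Correlation-based PCA over pixels and 8-bit principal-component images.

Pixels of an ``h x w`` RGB image form the rows of a feature matrix with
``c + d = 3 + 12 = 15`` columns: the raw channels followed by the color-index
planes.  PCA is run on the RGB block and the index block *separately*, and on
the correlation matrix rather than the covariance matrix, so that a column's
contribution does not depend on its scale (raw channels live on 0-255 while
index planes range from negative to positive values).

Component score fields are rescaled linearly to 0-255 gray images for
clustering and display.  A gray RGB component can be blended with a gray
index component by a user weight; the two weights sum to one and the blend is
performed on the rescaled gray fields (not raw scores), so neither block can
dominate through scale alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .color_indices import IndexStack

__all__ = [
    "RGB_COLUMNS",
    "FeatureMatrix",
    "PcScores",
    "PcImage",
    "build_feature_matrix",
    "pca_block",
    "scale_to_gray",
    "combine_pc",
    "snap_weight",
]

logger = logging.getLogger(__name__)

RGB_COLUMNS: Tuple[str, ...] = ("R", "G", "B")

#: Eigenvalues below this are treated as exactly zero.
EIGENVALUE_TOL = 1e-10

#: Step of the user-facing blend-weight grid.
WEIGHT_STEP = 0.02


@dataclass(frozen=True)
class FeatureMatrix:
    """Pixel-by-feature matrix; row ``k`` is pixel ``(k // w, k % w)``."""

    data: np.ndarray  # float64, shape (h * w, n_columns)
    columns: Tuple[str, ...]
    image_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if self.data.shape != (h * w, len(self.columns)):
            raise ValueError("feature matrix shape disagrees with columns/image shape")

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.columns.index(name)]


def build_feature_matrix(image: np.ndarray, indices: IndexStack) -> FeatureMatrix:
    """Stack raw channels and index planes into one row-major pixel matrix."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    if image.shape[:2] != (indices.h, indices.w):
        raise ValueError(
            f"image shape {image.shape[:2]} does not match index stack "
            f"shape {(indices.h, indices.w)}"
        )
    h, w = image.shape[:2]
    n = h * w
    cols = [image[:, :, ch].reshape(n).astype(np.float64) for ch in range(3)]
    cols.extend(indices.data[:, :, j].reshape(n) for j in range(indices.d))
    data = np.column_stack(cols)
    return FeatureMatrix(data=data, columns=RGB_COLUMNS + indices.names, image_shape=(h, w))


@dataclass(frozen=True)
class PcScores:
    """Per-block PCA result: eigenvalues, loadings and pixel score columns.

    Components are ordered by non-increasing eigenvalue; loading vectors are
    orthonormal, with the sign convention that each vector's
    largest-magnitude entry is positive (this removes the eigenvector sign
    ambiguity and makes the output bit-stable).
    """

    block: str
    eigenvalues: np.ndarray            # (p,), non-increasing
    loadings: np.ndarray               # (n_cols, p), orthonormal columns
    scores: np.ndarray                 # (n_pixels, p)
    columns: Tuple[str, ...]           # retained (non-constant) input columns
    image_shape: Tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def explained_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def score_field(self, component: int) -> np.ndarray:
        """Score column of a 1-based component reshaped to the image grid."""
        if not 1 <= component <= self.n_components:
            raise ValueError(
                f"component must be in 1..{self.n_components}, got {component}"
            )
        return self.scores[:, component - 1].reshape(self.image_shape)


def pca_block(matrix: FeatureMatrix, block: str) -> PcScores:
    """Correlation PCA on one column block (``"rgb"`` or ``"index"``).

    Columns are standardized to zero mean and unit variance before the
    eigen-decomposition, so the result is invariant to per-column rescaling.
    Zero-variance columns are dropped with a warning; if every column is
    constant the input is degenerate and an error is raised.
    """
    if block == "rgb":
        names = [c for c in matrix.columns if c in RGB_COLUMNS]
    elif block == "index":
        names = [c for c in matrix.columns if c not in RGB_COLUMNS]
    else:
        raise ValueError(f"block must be 'rgb' or 'index', got {block!r}")
    if not names:
        raise ValueError(f"feature matrix has no columns for block {block!r}")

    idx = [matrix.columns.index(c) for c in names]
    x = matrix.data[:, idx]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError(f"all columns of block {block!r} are constant; PCA is undefined")
    if not np.all(keep):
        dropped = [c for c, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance columns {dropped} from block {block!r}")
        names = [c for c, k in zip(names, keep) if k]
        x, mu, sd = x[:, keep], mu[keep], sd[keep]

    z = (x - mu) / sd
    corr = (z.T @ z) / z.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(np.abs(evals) < EIGENVALUE_TOL, 0.0, evals)
    # sign convention: largest-magnitude loading entry positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = z @ evecs
    return PcScores(
        block=block,
        eigenvalues=evals,
        loadings=evecs,
        scores=scores,
        columns=tuple(names),
        image_shape=matrix.image_shape,
    )


@dataclass(frozen=True)
class PcImage:
    """8-bit gray rendering of one component score field."""

    data: np.ndarray  # uint8, shape (h, w)
    provenance: Optional[Tuple] = None  # (block, component, weight) or similar

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape


def scale_to_gray(score_field: np.ndarray, provenance: Optional[Tuple] = None) -> PcImage:
    """Map a finite score field linearly onto 0-255 (min -> 0, max -> 255).

    Rounding is half-up.  A constant field has no range to map and becomes
    all zeros, with a warning.
    """
    field = np.asarray(score_field, dtype=np.float64)
    if not np.all(np.isfinite(field)):
        raise ValueError("score field contains non-finite values")
    lo = field.min()
    hi = field.max()
    if hi == lo:
        warnings.warn("constant score field; gray image set to all zeros")
        gray = np.zeros(field.shape, dtype=np.uint8)
    else:
        scaled = (field - lo) / (hi - lo) * 255.0
        gray = np.floor(scaled + 0.5).astype(np.uint8)
    return PcImage(data=gray, provenance=provenance)


def snap_weight(weight: float) -> float:
    """Snap a blend weight onto the 0.02 grid in [0, 1], warning if it moved."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"rgb_weight must be in [0, 1], got {weight}")
    snapped = np.floor(weight / WEIGHT_STEP + 0.5) * WEIGHT_STEP
    snapped = float(min(1.0, max(0.0, round(snapped, 2))))
    if abs(snapped - weight) > 1e-9:
        warnings.warn(f"rgb_weight {weight} snapped to grid value {snapped}")
    return snapped


def combine_pc(rgb_pc: PcImage, index_pc: PcImage, weight: float) -> PcImage:
    """Blend gray RGB and index component images: ``w * rgb + (1 - w) * index``.

    The blend is computed on the 0-255 gray fields and rescaled to 0-255
    again, so weight 0 reproduces the index image and weight 1 the RGB image
    exactly (both already span the full gray range).
    """
    if rgb_pc.shape != index_pc.shape:
        raise ValueError(
            f"component images differ in shape: {rgb_pc.shape} vs {index_pc.shape}"
        )
    weight = snap_weight(weight)
    field = weight * rgb_pc.data.astype(np.float64) + (1.0 - weight) * index_pc.data.astype(np.float64)
    provenance = ("combined", rgb_pc.provenance, index_pc.provenance, weight)
    return scale_to_gray(field, provenance=provenance)
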