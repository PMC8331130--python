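"""Pixel-wise K-Means on a gray component image and POI mask construction.

Clustering runs on the single gray value per pixel (the selected or blended
component image), i.e. it is one-dimensional over at most 256 distinct
levels.  In one dimension the optimal K-Means solution partitions the sorted
values into contiguous runs, so instead of iterative Lloyd refinement we
solve the weighted problem exactly by dynamic programming over the distinct
gray levels.  The result is deterministic, bit-reproducible, and attains the
global minimum within-cluster sum of squares for every ``k``.

Clusters are numbered by ascending cluster mean.  Selected cluster ids become
the binary pixels-of-interest (POI) mask; an optional elliptical region of
interest zeroes everything outside the ellipse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Tuple, Union

import numpy as np

from .decomposition import PcImage

__all__ = [
    "ClusterLabels",
    "EllipseRoi",
    "kmeans_labels",
    "select_clusters",
    "apply_elliptical_roi",
    "within_cluster_ss",
]

K_MIN, K_MAX = 1, 10


@dataclass(frozen=True)
class ClusterLabels:
    """Per-pixel cluster ids in ``[0, k)``, numbered by ascending mean gray."""

    labels: np.ndarray   # int32, shape (h, w)
    k: int
    means: np.ndarray    # (k,), strictly increasing

    def __post_init__(self) -> None:
        if self.means.size != self.k:
            raise ValueError("means length must equal k")


@dataclass(frozen=True)
class EllipseRoi:
    """Elliptical region of interest in pixel coordinates (rows downward)."""

    center: Tuple[float, float]      # (row, col)
    semi_axes: Tuple[float, float]   # (along rotated row axis, col axis)
    rotation: float = 0.0            # radians, counter-clockwise

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr = np.asarray(rows, dtype=np.float64) - self.center[0]
        dc = np.asarray(cols, dtype=np.float64) - self.center[1]
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        u = c * dr + s * dc
        v = -s * dr + c * dc
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _gray_of(pc: Union[PcImage, np.ndarray]) -> np.ndarray:
    gray = pc.data if isinstance(pc, PcImage) else np.asarray(pc)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D gray image")
    return gray


def _ckmeans_1d(values: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Exact weighted 1-D K-Means on sorted distinct values.

    Returns the index of the first value of each cluster (length ``k``).
    Standard O(u^2 k) dynamic program over contiguous partitions; ``u`` is at
    most 256 here so no speedup tricks are needed.
    """
    u = values.size
    w = weights.astype(np.float64)
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cwv = np.concatenate(([0.0], np.cumsum(w * values)))
    cwv2 = np.concatenate(([0.0], np.cumsum(w * values * values)))

    def sse(i: int, j: int) -> float:
        # weighted SSE of values[i..j] inclusive
        ww = cw[j + 1] - cw[i]
        s1 = cwv[j + 1] - cwv[i]
        s2 = cwv2[j + 1] - cwv2[i]
        return max(s2 - s1 * s1 / ww, 0.0)

    big = np.inf
    cost = np.full((k, u), big)
    back = np.zeros((k, u), dtype=np.int64)
    for j in range(u):
        cost[0, j] = sse(0, j)
    for m in range(1, k):
        for j in range(m, u):
            best, arg = big, m
            for i in range(m, j + 1):
                c = cost[m - 1, i - 1] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cost[m, j] = best
            back[m, j] = arg
    starts = np.empty(k, dtype=np.int64)
    j = u - 1
    for m in range(k - 1, -1, -1):
        i = back[m, j] if m > 0 else 0
        starts[m] = i
        j = i - 1
    return starts


def kmeans_labels(pc: Union[PcImage, np.ndarray], k: int, seed: int = 0) -> ClusterLabels:
    """Cluster gray values into ``k`` groups (exact 1-D K-Means).

    ``seed`` is accepted for interface stability but has no effect: the 1-D
    solver is exact and deterministic, so no random initialization exists to
    seed.  If ``k`` exceeds the number of distinct gray values it is reduced
    to that count with a warning.
    """
    del seed  # exact solver; kept for call-site compatibility
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k must be in {K_MIN}..{K_MAX}, got {k}")
    gray = _gray_of(pc)
    uniq, counts = np.unique(gray, return_counts=True)
    uniq = uniq.astype(np.float64)
    if k > uniq.size:
        warnings.warn(
            f"k={k} exceeds the {uniq.size} distinct gray values; reducing k"
        )
        k = int(uniq.size)
    starts = _ckmeans_1d(uniq, counts, k)
    # map each distinct value to its cluster; clusters are contiguous in
    # sorted order, hence already numbered by ascending mean
    value_cluster = np.zeros(uniq.size, dtype=np.int32)
    for m in range(1, k):
        value_cluster[starts[m]:] = m
    lut = np.zeros(256, dtype=np.int32)
    lut[uniq.astype(np.int64)] = value_cluster
    labels = lut[gray.astype(np.int64)]
    means = np.array([
        np.average(uniq[value_cluster == m], weights=counts[value_cluster == m])
        for m in range(k)
    ])
    return ClusterLabels(labels=labels, k=k, means=means)


def within_cluster_ss(gray: Union[PcImage, np.ndarray], labels: ClusterLabels) -> float:
    """Within-cluster sum of squares of a labeling over the gray image."""
    g = _gray_of(gray).astype(np.float64).ravel()
    lab = labels.labels.ravel()
    total = 0.0
    for m in range(labels.k):
        vals = g[lab == m]
        if vals.size:
            total += float(np.sum((vals - vals.mean()) ** 2))
    return total


def select_clusters(labels: ClusterLabels, selected: Iterable[int]) -> np.ndarray:
    """Binary POI mask: 1 where the pixel's cluster id is in ``selected``."""
    selected = set(int(s) for s in selected)
    if not selected:
        raise ValueError("at least one cluster must be selected")
    bad = [s for s in selected if not 0 <= s < labels.k]
    if bad:
        raise ValueError(f"cluster ids {sorted(bad)} outside 0..{labels.k - 1}")
    mask = np.isin(labels.labels, sorted(selected)).astype(np.uint8)
    return mask


def apply_elliptical_roi(mask: np.ndarray, roi: EllipseRoi) -> np.ndarray:
    """Zero mask pixels whose centers fall outside the elliptical region."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D binary mask")
    rows, cols = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    inside = roi.contains(rows, cols)
    return (mask.astype(bool) & inside).astype(np.uint8)
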