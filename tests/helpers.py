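"""Shared helpers for building POI masks and parameters from synthetic scenes."""

import numpy as np

from gridfree import (
    ParameterSet,
    SegmentThresholds,
    build_feature_matrix,
    compute_index_stack,
    kmeans_labels,
    pca_block,
    scale_to_gray,
    select_clusters,
)


def index_pc1_gray(image):
    """First index-block component of an image as an 8-bit gray image."""
    fm = build_feature_matrix(image, compute_index_stack(image))
    return scale_to_gray(pca_block(fm, "index").score_field(1))


def poi_clusters(labels):
    """Cluster ids covering the minority of pixels (objects cover < half)."""
    counts = np.bincount(labels.labels.ravel(), minlength=labels.k)
    return (int(np.argmin(counts)),)


def scene_params(image, k=2, thresholds=None):
    """ParameterSet whose cluster selection captures the scene's objects."""
    labels = kmeans_labels(index_pc1_gray(image), k)
    return ParameterSet(
        k=k,
        selected_clusters=poi_clusters(labels),
        thresholds=thresholds or SegmentThresholds(area_min=20, diag_min=4),
    )


def scene_poi_mask(image, k=2):
    """POI mask of a synthetic scene: index PC1 -> K-Means -> minority cluster."""
    labels = kmeans_labels(index_pc1_gray(image), k)
    return select_clusters(labels, poi_clusters(labels))


class UnionFind:
    """Minimal union-find used as the independent component-labeling oracle."""

    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def union_find_components(mask):
    """8-connected components via union-find; returns frozensets of pixels."""
    h, w = mask.shape
    uf = UnionFind(h * w)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((0, 1), (1, -1), (1, 0), (1, 1)):
                i2, j2 = i + di, j + dj
                if 0 <= i2 < h and 0 <= j2 < w and mask[i2, j2]:
                    uf.union(i * w + j, i2 * w + j2)
    comps = {}
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                comps.setdefault(uf.find(i * w + j), set()).add((i, j))
    return {frozenset(c) for c in comps.values()}


def disk_mask(shape, centers, radius):
    import numpy as _np

    yy, xx = _np.mgrid[0:shape[0], 0:shape[1]]
    m = _np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    return m
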