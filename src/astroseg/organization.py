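"""Spatial organization metrics for astrocyte somas.

Astrocytes tile the cortex in an even, minimally overlapping mosaic.  The
metrics here quantify that organization from soma coordinates: per-soma
distance to the nearest neighbor, mean distance to the k nearest neighbors
(k = 9 by default, matching the multi-neighbor analysis the organization
phenotype was measured with), pixel areas of thresholded cell clusters, and
the two-sample Kolmogorov-Smirnov statistic for comparing distance
distributions between conditions.  Distances are center-to-center with no
edge correction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "nearest_neighbor_distances",
    "k_neighbor_mean_distances",
    "cluster_areas",
    "ks_statistic",
]

_S8 = np.ones((3, 3), dtype=bool)


def _points(ps) -> np.ndarray:
    pts = np.asarray(getattr(ps, "points", ps), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    return pts


def nearest_neighbor_distances(ps) -> np.ndarray:
    """Per point, the Euclidean distance to its closest other point."""
    pts = _points(ps)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def k_neighbor_mean_distances(ps, k: int = 9) -> np.ndarray:
    """Per point, the mean distance to its k nearest other points."""
    pts = _points(ps)
    if not 1 <= k < len(pts):
        raise ValueError("need 1 <= k < number of points")
    d, _ = cKDTree(pts).query(pts, k=k + 1)
    return d[:, 1:].mean(axis=1)


def cluster_areas(img, blur_sigma: float, threshold: float, min_area: int = 500) -> list:
    """Areas of thresholded clusters strictly above ``min_area`` pixels.

    Multi-page input is maximum-projected, smoothed with an isotropic
    Gaussian of the given radius (0 disables blurring), binarized at
    ``threshold`` (exclusive), and 8-connected component areas strictly
    greater than ``min_area`` are returned in descending order.
    """
    a = np.asarray(getattr(img, "pixels", img), dtype=float)
    if a.ndim == 3:
        a = a.max(axis=0)
    if a.ndim != 2:
        raise ValueError("expected a 2-D image or a stack of 2-D pages")
    if blur_sigma < 0 or min_area < 1:
        raise ValueError("blur_sigma >= 0 and min_area >= 1 required")
    if blur_sigma > 0:
        a = ndi.gaussian_filter(a, sigma=blur_sigma)
    lab, n = ndi.label(a > threshold, structure=_S8)
    if n == 0:
        return []
    areas = np.bincount(lab.ravel())[1:]
    keep = sorted((int(x) for x in areas if x > min_area), reverse=True)
    return keep


def ks_statistic(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D.

    D = sup_x |F_a(x) - F_b(x)| over the two empirical CDFs; D in [0, 1].
    The statistic only — no p-value.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(fa - fb).max())
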