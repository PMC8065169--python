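"""Kinetic-energy fronts: detection, boundary overlap, segmentation, counts.

KE fronts — jets, persistent currents and large eddies — show up as cells of
elevated kinetic energy (0.5 |V|^2).  This module provides the validation
toolkit: percentile front thresholds over a reference period, the
one-point-dilated domain-boundary matrix, the boundary/front overlap
fraction, 1-D K-means segmentation of slot-mean KE into ordered intensity
clusters, per-pixel front-occurrence counts, and per-cell correlation maps
between two fields.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .grid import GriddedField

__all__ = [
    "FrontMask", "BoundaryMatrix",
    "ke_threshold", "front_mask", "boundary_matrix", "overlap_fraction",
    "kmeans_segment", "front_occurrence", "field_correlation_map",
]


@dataclass
class FrontMask:
    """Cells whose slot-mean KE exceeds a basin percentile threshold."""
    values: np.ndarray      # bool (nlat, nlon)
    threshold: float        # m2/s2
    q: float                # percentile used


@dataclass
class BoundaryMatrix:
    """Domain-boundary cells dilated by one grid point in each direction."""
    values: np.ndarray      # bool (nlat, nlon)


def ke_threshold(KE: GriddedField, q: float) -> float:
    """q-th percentile of KE over all ocean cells and all months.

    Uses the linear-interpolation percentile convention.
    """
    if not 0 < q < 100:
        raise ValueError("q must lie in (0, 100)")
    vals = KE.ocean_values()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all cells are masked; cannot compute a KE threshold")
    return float(np.percentile(vals, q, method="linear"))


def front_mask(KE: GriddedField, threshold: float, q: float = np.nan) -> FrontMask:
    """Front = slot-mean KE above the (reference-period) threshold."""
    mean = np.nanmean(KE.values, axis=0)
    vals = np.zeros(KE.mask.shape, dtype=bool)
    vals[KE.mask] = mean[KE.mask] > threshold
    return FrontMask(values=vals, threshold=threshold, q=q)


def boundary_matrix(
    labels: np.ndarray, mask: np.ndarray, coast_as_boundary: bool = False
) -> BoundaryMatrix:
    """Boundary cells (4-neighbor with a different label) dilated by a 3x3 kernel.

    Background (label 0) counts as its own label, so domain/background
    interfaces are boundaries.  By default a differing *land* neighbor does
    not create a boundary; set ``coast_as_boundary=True`` to count coastlines.
    The dilation (one binary dilation with the 8-connected structuring
    element) implements the one-grid-point augmentation in each direction,
    and is restricted to ocean cells.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    nlat, nlon = labels.shape
    raw = np.zeros_like(mask)
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        shifted_lab = np.full_like(labels, -9999)
        shifted_ocean = np.zeros_like(mask)
        src_i = slice(max(0, -di), nlat - max(0, di))
        dst_i = slice(max(0, di), nlat - max(0, -di))
        src_j = slice(max(0, -dj), nlon - max(0, dj))
        dst_j = slice(max(0, dj), nlon - max(0, -dj))
        shifted_lab[dst_i, dst_j] = labels[src_i, src_j]
        shifted_ocean[dst_i, dst_j] = mask[src_i, src_j]
        differs = mask & shifted_ocean & (labels != shifted_lab)
        if coast_as_boundary:
            differs |= mask & ~shifted_ocean & (shifted_lab != -9999)
        raw |= differs
    dilated = ndimage.binary_dilation(raw, structure=np.ones((3, 3), dtype=bool))
    return BoundaryMatrix(values=dilated & mask)


def overlap_fraction(boundary: BoundaryMatrix, front: FrontMask) -> float:
    """|boundary AND front| / |boundary|."""
    b = boundary.values
    f = front.values
    if b.shape != f.shape:
        raise ValueError("boundary and front are not on the same grid")
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("empty boundary matrix")
    return float((b & f).sum() / nb)


def kmeans_segment(mean_ke: np.ndarray, mask: np.ndarray, k: int = 4, seed: int = 0):
    """1-D K-means segmentation of slot-mean KE into k ordered intensity clusters.

    Clusters are relabeled by increasing centroid, so cluster k-1 is the
    maximum-intensity group (the KE-front indicator).  Returns
    (cluster_map, pixel_counts, centroids); the cluster map is -1 outside the
    ocean.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(mean_ke, dtype=float)[mask]
    if np.unique(vals).size < k:
        raise ValueError(
            f"cannot split {np.unique(vals).size} distinct KE values into {k} clusters"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    raw_labels = km.fit_predict(vals.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw_labels]
    cluster_map = np.full(mask.shape, -1, dtype=int)
    cluster_map[mask] = labels
    counts = np.bincount(labels, minlength=k)
    centroids = np.sort(km.cluster_centers_.ravel())
    return cluster_map, counts, centroids


def front_occurrence(KE: GriddedField, threshold: float) -> np.ndarray:
    """Per-cell count of months with KE above the reference threshold."""
    above = KE.values > threshold   # NaN compares False
    counts = above.sum(axis=0).astype(int)
    counts[~KE.mask] = 0
    return counts


def field_correlation_map(F1: GriddedField, F2: GriddedField):
    """Per-cell Pearson correlation of two co-gridded fields over time.

    Returns (corr_map, mean, variance, n_excluded): the spatial mean and
    (population) variance run over defined ocean cells; zero-variance cells
    are excluded and counted.
    """
    if not F1.congruent(F2):
        raise ValueError("fields are not congruent (grid/mask/time mismatch)")
    a = F1.ocean_values()
    b = F2.ocean_values()
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    ok = (na > 0) & (nb > 0) & np.isfinite(na) & np.isfinite(nb)
    corr = np.full(a.shape[1], np.nan)
    corr[ok] = np.einsum("ti,ti->i", a[:, ok], b[:, ok]) / (na[ok] * nb[ok])
    cmap = np.full(F1.mask.shape, np.nan)
    cmap[F1.mask] = corr
    mean = float(np.mean(corr[ok])) if ok.any() else float("nan")
    var = float(np.var(corr[ok])) if ok.any() else float("nan")
    return cmap, mean, var, int((~ok).sum())
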