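"""Seeded watershed instance segmentation of cell/non-cell predictions.

A binary prediction slice is turned into individual cells in four steps:
Euclidean distance transform of the foreground, Gaussian blur of the distance
map, h-maxima seed detection (suppressing maxima shallower than ``h`` so a
convex cell yields a single seed), and a marker-controlled watershed restricted
to the foreground.  A 3D variant of the same recipe serves as the
distance-transform-watershed baseline used for benchmark comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = ["Seg2DParams", "segment_slice", "apply_mask", "watershed3d_baseline"]


@dataclass(frozen=True)
class Seg2DParams:
    """Parameters of the per-slice watershed.

    gaussian_sigma : blur width in pixels applied to the distance map.
    h_maxima : depth threshold (distance-map units) below which local maxima
        are suppressed; larger h means fewer seeds per component.
    connectivity_2d : 4 or 8 pixel neighborhood for seed labeling and basins.
        4 keeps 1-px-wide user-drawn boundaries separating.
    mask_threshold : minimum in-ROI area proportion for a cell to survive
        ROI masking.
    """

    gaussian_sigma: float = 2.0
    h_maxima: float = 2.0
    connectivity_2d: int = 4
    mask_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.h_maxima < 0:
            raise ValueError("h_maxima must be >= 0")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")
        if not 0.0 <= self.mask_threshold <= 1.0:
            raise ValueError("mask_threshold must be in [0, 1]")


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), got values {vals[:10]}")
    return arr.astype(bool)


def _conn_structure(ndim: int, connectivity: int) -> np.ndarray:
    # connectivity 4/8 in 2D maps to scipy rank 1/2; in 3D, 6 vs 26 -> 1 vs 3
    rank = 1 if connectivity in (4, 6) else ndim
    return ndi.generate_binary_structure(ndim, rank)


def _relabel_rowmajor(markers: np.ndarray) -> np.ndarray:
    """Renumber marker labels 1..n by row-major order of first occurrence."""
    flat = markers.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return markers
    first = {}
    for idx in nz:
        lab = flat[idx]
        if lab not in first:
            first[lab] = idx
    order = sorted(first, key=first.get)
    lut = np.zeros(int(markers.max()) + 1, dtype=markers.dtype)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return lut[markers]


def _seeded_watershed(mask: np.ndarray, sigma: float, h: float,
                      structure: np.ndarray, ws_connectivity: int) -> np.ndarray:
    """Distance map -> blur -> h-maxima seeds -> watershed, any ndim."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    blurred = ndi.gaussian_filter(dist, sigma) if sigma > 0 else dist
    if h > 0:
        seeds = h_maxima(blurred, h, footprint=structure).astype(bool)
    else:
        seeds = blurred == ndi.maximum_filter(blurred, footprint=structure)
    seeds &= mask
    markers, _ = ndi.label(seeds, structure=structure)

    # components without any surviving maximum get one seed at their
    # distance-map argmax (first pixel in row-major order on ties)
    comps, n_comp = ndi.label(mask, structure=structure)
    if n_comp:
        seeded = np.unique(comps[markers > 0])
        missing = np.setdiff1d(np.arange(1, n_comp + 1), seeded)
        next_marker = int(markers.max()) + 1
        for comp_id in missing:
            inside = comps == comp_id
            flat_idx = np.flatnonzero(inside.ravel())
            best = flat_idx[np.argmax(blurred.ravel()[flat_idx])]
            markers.ravel()[best] = next_marker
            next_marker += 1

    markers = _relabel_rowmajor(markers)
    return watershed(-blurred, markers=markers, mask=mask,
                     connectivity=ws_connectivity).astype(np.int32)


def segment_slice(pred: np.ndarray, params: Seg2DParams | None = None) -> np.ndarray:
    """Segment one binary prediction slice into a 2D label image.

    Background pixels stay 0; every foreground connected component is covered
    by at least one label; labels are consecutive integers starting at 1,
    numbered in row-major order of each seed's first pixel so output is
    deterministic.
    """
    params = params or Seg2DParams()
    mask = _check_binary(pred, "prediction")
    if mask.ndim != 2:
        raise ValueError("segment_slice expects a 2D slice")
    structure = _conn_structure(2, params.connectivity_2d)
    ws_conn = 1 if params.connectivity_2d == 4 else 2
    return _seeded_watershed(mask, params.gaussian_sigma, params.h_maxima,
                             structure, ws_conn)


def apply_mask(labels: np.ndarray, roi: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Zero every cell whose in-ROI area proportion is strictly below threshold.

    A cell with proportion exactly equal to the threshold is kept.
    """
    labels = np.asarray(labels)
    roi = _check_binary(roi, "ROI mask")
    if labels.shape != roi.shape:
        raise ValueError(f"shape mismatch: labels {labels.shape} vs roi {roi.shape}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    max_lab = int(labels.max(initial=0))
    if max_lab == 0:
        return labels.copy()
    total = np.bincount(labels.ravel(), minlength=max_lab + 1)
    inside = np.bincount(labels[roi].ravel(), minlength=max_lab + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = inside / total
    keep = np.ones(max_lab + 1, dtype=bool)
    present = total > 0
    keep[present] = proportion[present] >= threshold
    keep[0] = False
    lut = np.where(keep, np.arange(max_lab + 1), 0)
    lut[0] = 0
    return lut[labels].astype(labels.dtype)


def watershed3d_baseline(pred: np.ndarray, params: Seg2DParams | None = None,
                         connectivity_3d: int = 26) -> np.ndarray:
    """3D distance-transform watershed over the whole stack (baseline method).

    Applies the same distance transform / blur / h-maxima / watershed recipe
    volumetrically.  Used as the comparison baseline: on anisotropic stacks
    with missing boundaries it merges and mis-places boundaries more often
    than the slice-wise watershed plus cross-slice linking.
    """
    params = params or Seg2DParams()
    mask = _check_binary(pred, "prediction")
    if mask.ndim != 3:
        raise ValueError("watershed3d_baseline expects a 3D stack")
    structure = _conn_structure(3, connectivity_3d)
    ws_conn = 1 if connectivity_3d == 6 else 3
    return _seeded_watershed(mask, params.gaussian_sigma, params.h_maxima,
                             structure, ws_conn)
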