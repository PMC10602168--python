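"""Otsu segmentation of tracer hyperintensity and boundary extraction.

Within a manually drawn ROI the tissue is split into tracer / non-tracer
classes by Otsu's threshold (256 bins over the observed intensity range;
the higher-intensity class is the tracer).  The tracer region's boundary is
the set of mask voxels with at least one face-adjacent (6-connectivity)
neighbor outside the mask or on the lattice edge, returned as voxel-center
coordinates in physical mm.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import (DegenerateInputError, GeometryError, ImageVolume,
                   TracerFlowError, TracerSurface)

__all__ = ["otsu_threshold", "segment_tracer", "extract_boundary",
           "largest_component"]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def otsu_threshold(values, bins: int = 256) -> float:
    """Threshold maximizing between-class variance over a binned histogram.

    The histogram spans the observed range of ``values`` with ``bins``
    equal-width bins; the returned threshold is the center of the bin at
    which the between-class variance is maximal, with ties broken toward
    the lower threshold.  Classification convention: tracer class is
    ``value > threshold``.
    """
    values = np.asarray(values, float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError("Otsu needs at least two distinct values")
    counts, edges = np.histogram(values, bins=bins)
    centers = edges[:-1] + np.diff(edges) / 2.0

    w = counts.astype(float)
    omega0 = np.cumsum(w)
    omega1 = omega0[-1] - omega0
    mu_cum = np.cumsum(w * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_cum[-1] - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1])  # a cut after the last bin is no cut
    # runs of empty bins yield identical partitions whose recomputed
    # objectives differ only by rounding; evaluating each distinct partition
    # once, at its lowest cut, keeps the tie-break (toward the lower
    # threshold) exact
    candidates = np.flatnonzero(counts[:-1] > 0)
    best = candidates[int(np.argmax(sigma_b[candidates]))]
    return float(centers[best])


def segment_tracer(volume: ImageVolume, roi: np.ndarray) -> np.ndarray:
    """Binary tracer mask inside ``roi``: intensity above the ROI's Otsu cut.

    Raises on an empty ROI or constant intensities inside it.
    """
    roi = np.asarray(roi, bool)
    if roi.shape != volume.shape:
        raise GeometryError("ROI shape must match the volume")
    if not roi.any():
        raise TracerFlowError("ROI is empty")
    inside = volume.values[roi]
    thr = otsu_threshold(inside)
    mask = np.zeros(volume.shape, bool)
    mask[roi] = inside > thr
    return mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Restrict a mask to its largest 26-connected component."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n <= 1:
        return mask.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def extract_boundary(mask: np.ndarray, spacing, time_min: float = float("nan")
                     ) -> TracerSurface:
    """Surface of a binary mask as voxel-center points in mm.

    A voxel belongs to the boundary when it is in the mask and has a
    face-adjacent neighbor outside the mask, or lies on the lattice edge
    (equivalently: the mask minus its 6-connectivity erosion).
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise GeometryError("mask must be 3D")
    if not mask.any():
        raise TracerFlowError("cannot extract the boundary of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE,
                                      border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary).astype(float)
    points = idx * np.asarray(spacing, float)
    return TracerSurface(points=points, time_min=time_min)


def check_surface_growth(surfaces) -> bool:
    """Whether surface sizes increase strictly over time (N1 < N2 < N3).

    A spreading tracer should produce strictly growing surfaces; on noisy
    real data a violation is reported as a warning rather than an error.
    """
    ns = [s.n_points for s in surfaces]
    growing = all(a < b for a, b in zip(ns, ns[1:]))
    if not growing:
        warnings.warn(f"surface point counts are not strictly increasing: {ns}",
                      stacklevel=2)
    return growing
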