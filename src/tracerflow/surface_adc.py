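"""Pseudo-ADC (ADC*) from the propagation of segmented tracer surfaces.

For each point on the earlier surface, the travel distance is the Euclidean
distance in mm to the closest point of the later surface; with elapsed time
``t`` (ms) and dimensionality ``d = 3``, each point contributes

    ADC* = dist^2 / (2 d t)        [mm^2/ms]

Per-point values from every consecutive surface pair are pooled, and the
region estimate is the pooled mean with its standard error.  Because the
tracer boundary moves under diffusion *and* any convective bulk flow, ADC*
exceeding the purely diffusive ADC predicted for the molecule is evidence
of bulk flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import MS_PER_MIN, DiffusivityEstimate, TracerFlowError, TracerSurface
from .segmentation import check_surface_growth, extract_boundary, segment_tracer

__all__ = ["nearest_distances", "pointwise_adcstar", "SurfacePairResult",
           "surfaces_from_series", "region_adcstar"]


def nearest_distances(earlier: TracerSurface, later: TracerSurface) -> np.ndarray:
    """One distance (mm) per point of ``earlier``: to its nearest point on
    ``later``.  Directional (earlier -> later), not symmetric."""
    if earlier.n_points < 1 or later.n_points < 1:
        raise TracerFlowError("both surfaces must be nonempty")
    tree = cKDTree(later.points)
    dist, _ = tree.query(earlier.points, k=1)
    return np.asarray(dist, float)


def pointwise_adcstar(distances, dt_ms: float, d_dim: int = 3) -> np.ndarray:
    """Per-point pseudo-ADC values ``dist^2 / (2 * d_dim * dt_ms)``."""
    if dt_ms <= 0:
        raise TracerFlowError("elapsed time between surfaces must be positive")
    if d_dim < 1:
        raise TracerFlowError("dimensionality must be >= 1")
    distances = np.asarray(distances, float)
    if np.any(distances < 0):
        raise TracerFlowError("distances must be non-negative")
    return distances ** 2 / (2.0 * d_dim * dt_ms)


@dataclass
class SurfacePairResult:
    """Per-point travel distances and ADC* values for one surface pair."""

    distances: np.ndarray
    dt_ms: float
    d_dim: int
    adcstar_values: np.ndarray
    time_from_min: float
    time_to_min: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.adcstar_values))

    @property
    def n(self) -> int:
        return int(self.adcstar_values.size)


def _pair_result(earlier: TracerSurface, later: TracerSurface,
                 d_dim: int = 3) -> SurfacePairResult:
    dt_ms = (later.time_min - earlier.time_min) * MS_PER_MIN
    dist = nearest_distances(earlier, later)
    return SurfacePairResult(distances=dist, dt_ms=dt_ms, d_dim=d_dim,
                             adcstar_values=pointwise_adcstar(dist, dt_ms, d_dim),
                             time_from_min=earlier.time_min,
                             time_to_min=later.time_min)


def surfaces_from_series(series, rois, use_largest_component: bool = False):
    """Segment each timepoint inside its ROI and extract tracer surfaces.

    ``rois`` is a single boolean mask (reused at every timepoint, as when
    one manual ROI is drawn once) or a list with one mask per timepoint.
    """
    volumes = series.volumes
    if isinstance(rois, np.ndarray):
        rois = [rois] * len(volumes)
    if len(rois) != len(volumes):
        raise TracerFlowError("need one ROI per timepoint (or a single shared ROI)")
    surfaces = []
    for vol, roi in zip(volumes, rois):
        try:
            mask = segment_tracer(vol, roi)
            if use_largest_component:
                from .segmentation import largest_component
                mask = largest_component(mask)
            surfaces.append(extract_boundary(mask, vol.spacing, time_min=vol.time_min))
        except TracerFlowError as err:
            raise TracerFlowError(
                f"segmentation failed at t={vol.time_min} min: {err}") from err
    return surfaces


def region_adcstar(series, rois, region: str = "roi", d_dim: int = 3,
                   use_largest_component: bool = False) -> DiffusivityEstimate:
    """Region-level ADC* from a timepoint series and ROI(s).

    Segments every timepoint, extracts surfaces, computes per-point ADC*
    for each consecutive surface pair (S1->S2, S2->S3, ...), pools all
    per-point values, and returns their mean and standard error.  The pair
    means are kept in ``extra["pairs"]`` for reporting.
    """
    surfaces = surfaces_from_series(series, rois,
                                    use_largest_component=use_largest_component)
    if len(surfaces) < 2:
        raise TracerFlowError("ADC* needs at least two timepoints")
    check_surface_growth(surfaces)
    pairs = [_pair_result(a, b, d_dim=d_dim)
             for a, b in zip(surfaces, surfaces[1:])]
    pooled = np.concatenate([p.adcstar_values for p in pairs])
    n = pooled.size
    se = float(np.std(pooled, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DiffusivityEstimate(
        region=region, value=float(np.mean(pooled)), se=se,
        method="surface_adcstar", n=n,
        extra={"pairs": [{"t_from_min": p.time_from_min, "t_to_min": p.time_to_min,
                          "mean": p.mean, "n": p.n} for p in pairs],
               "surface_counts": [s.n_points for s in surfaces]})
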