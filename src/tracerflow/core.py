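"""Shared containers and exceptions for the tracer-transport pipeline.

All physical coordinates are voxel-center positions, ``index * spacing``,
in millimetres, in the volume's own frame (inputs are assumed co-registered,
so no affine re-orientation is performed).  Diffusivities are carried in
mm^2/ms throughout; simulator time runs in minutes with 1 min = 6e4 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MS_PER_MIN = 6.0e4

#: Tags an ImageVolume may carry to document what its values mean.
VOLUME_KINDS = ("concentration", "t1_signal", "dw_signal", "scalar_map")


class TracerFlowError(Exception):
    """Base class for errors raised by this package."""


class GeometryError(TracerFlowError):
    """Shapes, spacings or regions are mutually inconsistent."""


class FormatError(TracerFlowError):
    """A file exists but does not describe a usable 3D volume."""


class DegenerateInputError(TracerFlowError):
    """Input is formally valid but carries no usable signal (e.g. constant)."""


class AcquisitionError(TracerFlowError):
    """A diffusion-weighted acquisition cannot identify the tensor."""


class StatisticsError(TracerFlowError):
    """A statistical routine received groups it cannot test."""


class PipelineError(TracerFlowError):
    """A pipeline stage failed; carries subject / region / stage context."""

    def __init__(self, message: str, *, subject: str | None = None,
                 region: str | None = None, stage: str | None = None):
        ctx = ", ".join(f"{k}={v}" for k, v in
                        (("subject", subject), ("region", region), ("stage", stage))
                        if v is not None)
        super().__init__(f"{message} [{ctx}]" if ctx else message)
        self.subject, self.region, self.stage = subject, region, stage


@dataclass
class ImageVolume:
    """A 3D scalar lattice with physical voxel spacing and a timestamp.

    Parameters
    ----------
    values
        3D array of finite scalars.
    spacing
        Voxel size (dx, dy, dz) in mm, strictly positive.
    time_min
        Minutes after the end of tracer infusion (may be ``nan`` for
        volumes without a meaningful timestamp, e.g. scalar maps).
    kind
        One of :data:`VOLUME_KINDS`, purely documentary.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    time_min: float = float("nan")
    kind: str = "t1_signal"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid_as(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class TracerSurface:
    """Boundary of a segmented tracer region as points in physical mm.

    ``points`` has shape (n_points, 3); coordinates are voxel centers.
    """

    points: np.ndarray
    time_min: float

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GeometryError("surface points must be an (N, 3) array")
        if self.points.shape[0] < 1:
            raise DegenerateInputError("a tracer surface needs at least one point")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class DiffusivityEstimate:
    """A region-level diffusivity in mm^2/ms with its dispersion.

    ``method`` distinguishes the boundary-propagation estimate
    (``surface_adcstar``) from the tortuosity-scaled DTI prediction
    (``dti_scaled``).  ``n`` counts the samples that went into the mean
    (surface points for ADC*, ROI voxels for DTI).
    """

    region: str
    value: float
    se: float
    method: str
    n: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("diffusivity estimates must be non-negative")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if self.method not in ("surface_adcstar", "dti_water", "dti_scaled"):
            raise ValueError(f"unknown estimate method {self.method!r}")

    def as_dict(self) -> dict:
        d = {"region": self.region, "value": self.value, "se": self.se,
             "method": self.method, "n": int(self.n)}
        d.update(self.extra)
        return d


def voxel_centers_mm(shape: tuple[int, int, int],
                     spacing: tuple[float, float, float]) -> tuple[np.ndarray, ...]:
    """Per-axis voxel-center coordinate vectors in mm (index * spacing)."""
    return tuple(np.arange(n) * s for n, s in zip(shape, spacing))
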