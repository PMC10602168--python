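"""Diffusion-tensor estimation and scalar maps (FA, ADC, axial, radial).

The tensor is fit per voxel by ordinary log-linear least squares on the
monoexponential model ``ln(S_g / S0) = -b g^T D g`` over >= 6 unit gradient
directions, followed by eigendecomposition with descending sort
(lambda1 >= lambda2 >= lambda3).  Scalar maps follow the standard
definitions:

    FA   = sqrt(1/2) * sqrt(sum_{i<j} (li - lj)^2) / sqrt(sum_i li^2)
    ADC  = (l1 + l2 + l3) / 3           (mean diffusivity)
    Daxi = l1                           (axial / parallel)
    Drad = (l2 + l3) / 2                (radial / perpendicular)

so that ADC = (Daxi + 2 Drad) / 3 holds identically.  No positivity
constraint is imposed by the fit; negative eigenvalues are clamped to zero
for the scalar maps and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (AcquisitionError, DiffusivityEstimate, GeometryError,
                   ImageVolume, TracerFlowError)

__all__ = [
    "DEFAULT_DIRECTIONS", "DwiAcquisition", "TensorMap", "fit_tensor",
    "fa_from_eigenvalues", "adc_from_eigenvalues", "daxi_drad", "roi_mean_adc",
]

#: Classic six-direction scheme: +-x+-y, +-y+-z, +-x+-z pairs, normalized.
DEFAULT_DIRECTIONS = np.array([
    [1, 1, 0], [1, -1, 0],
    [0, 1, 1], [0, 1, -1],
    [1, 0, 1], [-1, 0, 1],
], dtype=float) / np.sqrt(2.0)


def design_matrix(directions: np.ndarray) -> np.ndarray:
    """Rows ``[gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]`` so that
    ``row . (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) = g^T D g``."""
    g = np.asarray(directions, float)
    return np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


@dataclass
class DwiAcquisition:
    """One unweighted volume plus one DW volume per gradient direction."""

    s0_volume: ImageVolume
    b_value: float
    directions: np.ndarray
    dw_volumes: list[ImageVolume]

    def __post_init__(self):
        self.directions = np.atleast_2d(np.asarray(self.directions, float))
        if self.b_value <= 0:
            raise AcquisitionError("b_value must be positive")
        n = self.directions.shape[0]
        if n < 6:
            raise AcquisitionError(f"need >= 6 gradient directions, got {n}")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise AcquisitionError("gradient directions must have unit norm (tol 1e-6)")
        if len(self.dw_volumes) != n:
            raise AcquisitionError("one DW volume is required per direction")
        if np.linalg.matrix_rank(design_matrix(self.directions)) < 6:
            raise AcquisitionError(
                "direction set is rank-deficient; the tensor is not identifiable")
        for vol in self.dw_volumes:
            if not vol.same_grid_as(self.s0_volume):
                raise GeometryError("all DWI volumes must share shape and spacing")

    @property
    def shape(self):
        return self.s0_volume.shape

    @property
    def spacing(self):
        return self.s0_volume.spacing


@dataclass
class TensorMap:
    """Voxelwise symmetric diffusion tensors with derived scalar maps.

    ``tensors`` has shape grid + (3, 3); ``eigenvalues`` grid + (3,), sorted
    descending.  Scalar maps are computed from eigenvalues clamped at zero;
    ``valid`` marks voxels where a fit was possible and ``negative_eig``
    flags voxels whose raw fit produced a negative eigenvalue.
    """

    tensors: np.ndarray
    spacing: tuple[float, float, float]
    eigenvalues: np.ndarray = None
    valid: np.ndarray = None
    negative_eig: np.ndarray = None
    fa: np.ndarray = field(init=False, default=None)
    adc: np.ndarray = field(init=False, default=None)
    daxi: np.ndarray = field(init=False, default=None)
    drad: np.ndarray = field(init=False, default=None)

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, float)
        grid = self.tensors.shape[:3]
        if self.tensors.shape != grid + (3, 3):
            raise GeometryError("tensors must have shape grid + (3, 3)")
        if self.valid is None:
            self.valid = np.ones(grid, bool)
        if self.eigenvalues is None:
            # eigh returns ascending; flip to descending
            evals = np.linalg.eigvalsh(self.tensors)[..., ::-1]
            self.eigenvalues = evals
        if self.negative_eig is None:
            self.negative_eig = self.eigenvalues[..., 2] < 0
        self._fill_scalar_maps()

    def _fill_scalar_maps(self):
        lam = np.clip(self.eigenvalues, 0.0, None)
        l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
        self.adc = (l1 + l2 + l3) / 3.0
        self.daxi = l1
        self.drad = (l2 + l3) / 2.0
        num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
        den = l1 ** 2 + l2 ** 2 + l3 ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(0.5 * num / den)
        fa = np.where(den > 0, fa, np.nan)
        self.fa = np.clip(fa, 0.0, 1.0)

    @classmethod
    def from_tensors(cls, tensors, spacing) -> "TensorMap":
        return cls(tensors=tensors, spacing=tuple(spacing))

    @property
    def shape(self):
        return self.tensors.shape[:3]

    def scalar_volume(self, name: str) -> ImageVolume:
        arr = {"fa": self.fa, "adc": self.adc, "daxi": self.daxi,
               "drad": self.drad}[name]
        return ImageVolume(np.nan_to_num(arr), self.spacing, kind="scalar_map")


# ---------------------------------------------------------------------------
# eigenvalue arithmetic
# ---------------------------------------------------------------------------

def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy in [0, 1]; undefined (error) for all-zero input."""
    l1, l2, l3 = (np.asarray(x, float) for x in (l1, l2, l3))
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    if np.any(den == 0):
        raise TracerFlowError("FA is undefined for all-zero eigenvalues")
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    return np.clip(np.sqrt(0.5 * num / den), 0.0, 1.0)[()]


def adc_from_eigenvalues(l1, l2, l3):
    """Mean diffusivity (l1 + l2 + l3) / 3."""
    return (np.asarray(l1, float) + np.asarray(l2, float) + np.asarray(l3, float))[()] / 3.0


def daxi_drad(l1, l2, l3):
    """Axial (= l1) and radial (= (l2 + l3)/2) diffusivity.

    Eigenvalues must already be sorted descending; unsorted input is a
    contract violation.
    """
    l1, l2, l3 = (np.asarray(x, float) for x in (l1, l2, l3))
    if np.any(l1 < l2) or np.any(l2 < l3):
        raise TracerFlowError("eigenvalues must be sorted descending (l1 >= l2 >= l3)")
    return l1[()], ((l2 + l3) / 2.0)[()]


# ---------------------------------------------------------------------------
# tensor fitting
# ---------------------------------------------------------------------------

def fit_tensor(dwi: DwiAcquisition) -> TensorMap:
    """Estimate the voxelwise tensor by log-linear least squares.

    Voxels with non-positive S0 or any non-positive DW signal are excluded
    via the validity mask (their tensor is left at zero).
    """
    s0 = dwi.s0_volume.values
    dw = np.stack([v.values for v in dwi.dw_volumes], axis=-1)  # grid + (n,)
    valid = (s0 > 0) & np.all(dw > 0, axis=-1)

    B = design_matrix(dwi.directions)           # (n, 6)
    pinv = np.linalg.pinv(B)                    # (6, n)
    grid = s0.shape
    y = np.zeros(grid + (B.shape[0],))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = dw / s0[..., None]
        np.log(ratio, out=y, where=valid[..., None])
    y = -y / dwi.b_value
    comps = np.einsum("kn,...n->...k", pinv, y)  # (Dxx,Dyy,Dzz,Dxy,Dxz,Dyz)
    comps[~valid] = 0.0

    tensors = np.zeros(grid + (3, 3))
    tensors[..., 0, 0] = comps[..., 0]
    tensors[..., 1, 1] = comps[..., 1]
    tensors[..., 2, 2] = comps[..., 2]
    tensors[..., 0, 1] = tensors[..., 1, 0] = comps[..., 3]
    tensors[..., 0, 2] = tensors[..., 2, 0] = comps[..., 4]
    tensors[..., 1, 2] = tensors[..., 2, 1] = comps[..., 5]

    evals = np.linalg.eigvalsh(tensors)[..., ::-1]
    return TensorMap(tensors=tensors, spacing=dwi.spacing, eigenvalues=evals,
                     valid=valid)


def roi_mean_adc(tensor_map: TensorMap, roi: np.ndarray,
                 region: str = "roi") -> DiffusivityEstimate:
    """Mean +/- SE of the water ADC over valid ROI voxels."""
    roi = np.asarray(roi, bool)
    if roi.shape != tensor_map.shape:
        raise GeometryError("ROI shape must match the tensor map")
    sel = roi & tensor_map.valid
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise TracerFlowError("ROI does not intersect the validity mask")
    vals = tensor_map.adc[sel]
    se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DiffusivityEstimate(region=region, value=float(np.mean(vals)), se=se,
                               method="dti_water", n=n)
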