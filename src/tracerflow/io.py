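"""NIfTI volume I/O, geometry validation and timepoint-series assembly.

Volumes are stored as NIfTI-1 with voxel spacing in the header; acquisition
times (minutes post infusion-end) come from a sidecar CSV manifest
``path,time_min`` because volumetric headers carry no reliable
acquisition-delay field.  DW acquisitions use a manifest
``path,bval,gx,gy,gz`` in which the ``bval == 0`` row names the unweighted
volume.  Physical coordinates are voxel centers, ``index * spacing``, in
the volume's own frame; inputs are assumed co-registered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FormatError, GeometryError, ImageVolume, TracerFlowError
from .dti import DwiAcquisition

__all__ = ["load_volume", "save_volume", "load_mask", "save_mask",
           "VolumeSeries", "assemble_series", "load_series_manifest",
           "load_dwi_manifest"]


def _read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as err:  # corrupt file
        raise FormatError(f"cannot read {path}: {err}") from err
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms} in header")
    return np.asarray(data, float), tuple(float(z) for z in zooms)


def load_volume(path, time_min: float = float("nan"),
                kind: str = "t1_signal") -> ImageVolume:
    """Read a 3D NIfTI volume; attach ``time_min`` from the caller."""
    data, spacing = _read_nifti(path)
    return ImageVolume(data, spacing, time_min=float(time_min), kind=kind)


def save_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 with spacing on the affine diagonal."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    """Read a {0,1} NIfTI mask as a boolean array."""
    data, _ = _read_nifti(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise FormatError(f"{path}: mask values must be 0/1, found {uniq[:5]}")
    return data > 0.5


def save_mask(mask: np.ndarray, spacing, path) -> None:
    save_volume(ImageVolume(np.asarray(mask, float), spacing, kind="scalar_map"),
                path)


@dataclass
class VolumeSeries:
    """>= 2 volumes on a common grid, sorted by strictly increasing time."""

    volumes: list

    def __post_init__(self):
        if len(self.volumes) < 2:
            raise TracerFlowError("a series needs at least two timepoints")
        self.volumes = sorted(self.volumes, key=lambda v: v.time_min)
        first = self.volumes[0]
        if not np.isfinite(first.time_min):
            raise TracerFlowError("every volume in a series needs a finite time_min")
        for prev, cur in zip(self.volumes, self.volumes[1:]):
            if not np.isfinite(cur.time_min):
                raise TracerFlowError("every volume in a series needs a finite time_min")
            if cur.time_min == prev.time_min:
                raise TracerFlowError(f"duplicate timepoint {cur.time_min} min")
            if not cur.same_grid_as(first):
                raise GeometryError("series volumes must share shape and spacing")

    @property
    def times_min(self) -> list:
        return [v.time_min for v in self.volumes]

    @property
    def spacing(self):
        return self.volumes[0].spacing

    @property
    def shape(self):
        return self.volumes[0].shape


def assemble_series(volumes) -> VolumeSeries:
    """Sort volumes by time and enforce the series invariants."""
    return VolumeSeries(volumes=list(volumes))


def load_series_manifest(manifest_path) -> VolumeSeries:
    """Load a timepoint series from a CSV manifest with columns
    ``path,time_min``; relative paths resolve against the manifest."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("path", "time_min"):
        if col not in df.columns:
            raise FormatError(f"series manifest needs a {col!r} column")
    volumes = [load_volume(_resolve(manifest_path, row["path"]),
                           time_min=float(row["time_min"]))
               for _, row in df.iterrows()]
    return assemble_series(volumes)


def load_dwi_manifest(manifest_path) -> DwiAcquisition:
    """Load a DW acquisition from a CSV manifest ``path,bval,gx,gy,gz``.

    Exactly one row must carry ``bval == 0`` (the unweighted volume); the
    remaining rows must share a common positive b-value.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("path", "bval", "gx", "gy", "gz"):
        if col not in df.columns:
            raise FormatError(f"DWI manifest needs a {col!r} column")
    b0 = df[df["bval"] == 0]
    dw = df[df["bval"] > 0]
    if len(b0) != 1:
        raise FormatError("DWI manifest must contain exactly one bval == 0 row")
    bvals = dw["bval"].unique()
    if len(bvals) != 1:
        raise FormatError(f"expected a single nonzero b-value, found {bvals}")
    s0_volume = load_volume(_resolve(manifest_path, b0.iloc[0]["path"]),
                            kind="dw_signal")
    directions = dw[["gx", "gy", "gz"]].to_numpy(float)
    dw_volumes = [load_volume(_resolve(manifest_path, row["path"]), kind="dw_signal")
                  for _, row in dw.iterrows()]
    return DwiAcquisition(s0_volume=s0_volume, b_value=float(bvals[0]),
                          directions=directions, dw_volumes=dw_volumes)


def _resolve(manifest_path: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else manifest_path.parent / p
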