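"""Voxel-grid containers and NIfTI-1 round-trip I/O.

World coordinates are centimetres on right-handed axes with the origin at
the outer corner of voxel ``(0, 0, 0)``; voxel centres sit at
``origin + (index + 0.5) * voxel_size``.  NIfTI stores spacings in
millimetres and places the affine translation on the first voxel *centre*;
both conventions are converted on read/write so that a write→read cycle
preserves values, voxel size and origin exactly (densities are stored as
float64, masks as uint8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "DensityVolume",
    "EffectiveDensityVolume",
    "TargetROI",
    "write_volume",
    "read_volume",
    "read_roi",
]


def _as_triple(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass
class DensityVolume:
    """3D mass-density grid (g/cm^3) with voxel size and corner origin in cm."""

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density grid contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("density grid contains negative values")
        self.voxel_size = _as_triple(self.voxel_size)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid along each axis (cm)."""
        return np.asarray(self.shape) * self.voxel_size

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Centre coordinates of all voxels along one axis (cm)."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]


@dataclass
class EffectiveDensityVolume(DensityVolume):
    """Water-equivalent density grid: mass density scaled by the
    tissue-to-water mass stopping-power ratio.  Line integrals of it give
    water-equivalent path length in cm."""


@dataclass
class TargetROI:
    """Binary target mask on the same grid as its density volume.

    Carries grid geometry so downstream beam/spot computations need only
    the ROI.  ``index`` is the target index *i* used in energy matrices.
    """

    mask: np.ndarray
    label: str
    index: int
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")
        self.voxel_size = _as_triple(self.voxel_size)
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def mask_centroid(self) -> np.ndarray:
        """Centroid of the mask voxel centres (cm)."""
        idx = np.argwhere(self.mask)
        return self.origin + (idx.mean(axis=0) + 0.5) * self.voxel_size


def _affine(voxel_size_cm: np.ndarray, origin_cm: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_cm * 10.0)
    aff[:3, 3] = (origin_cm + 0.5 * voxel_size_cm) * 10.0
    return aff


def write_volume(obj: DensityVolume | TargetROI, path) -> None:
    """Write a density volume (float64) or ROI mask (uint8) as NIfTI-1."""
    if isinstance(obj, TargetROI):
        data = obj.mask.astype(np.uint8)
    else:
        data = obj.values.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(obj.voxel_size, obj.origin))
    nib.save(img, str(path))


def _read_geometry(img) -> tuple[np.ndarray, np.ndarray]:
    aff = img.affine
    vs = np.abs(np.diag(aff)[:3]) / 10.0
    origin = aff[:3, 3] / 10.0 - 0.5 * vs
    return vs, origin


def read_volume(path) -> DensityVolume:
    """Read a NIfTI density volume back into the cm/corner-origin convention."""
    img = nib.load(str(path))
    vs, origin = _read_geometry(img)
    return DensityVolume(np.asarray(img.dataobj, dtype=float), vs, origin)


def read_roi(path, volume: DensityVolume, label: str = "", index: int = 0) -> TargetROI:
    """Read a NIfTI mask and pair it with its density volume.

    Raises ``ValueError`` if the mask grid does not match the volume grid.
    """
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    if mask.shape != volume.shape:
        raise ValueError(
            f"ROI {label or path!r} shape {mask.shape} does not match "
            f"volume shape {volume.shape}"
        )
    vs, origin = _read_geometry(img)
    return TargetROI(mask, label=label, index=index, voxel_size=vs, origin=origin)
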