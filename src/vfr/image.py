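"""Grid-aligned volume containers and NIfTI-1 I/O.

Volumes live on isotropic (or at least axis-aligned) voxel grids; world
coordinates are millimetres in a RAS+ frame with the origin at the corner of
voxel (0, 0, 0).  Axis order is (x, y, z); the z axis is the scanner (and
vertebral) axial direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["QCTImage", "SegmentationMask", "load_volume", "load_mask"]

#: unit tag for raw scanner volumes
UNITS_HU = "HU"
#: unit tag for densitometrically calibrated volumes (rho_QCT)
UNITS_BMD = "g/cm3"


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in np.atleast_1d(spacing).ravel())
    if len(spacing) == 1:
        spacing = spacing * 3
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing}")
    return spacing


@dataclass
class QCTImage:
    """A 3D scalar CT volume with voxel spacing and a unit tag.

    Parameters
    ----------
    data
        3D float array, axis order (x, y, z).
    spacing
        Voxel edge lengths in mm.
    units
        ``"HU"`` for raw scans, ``"g/cm3"`` once densitometrically calibrated.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    units: str = UNITS_HU
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("QCTImage data must be 3D")
        self.spacing = _check_spacing(self.spacing)
        if self.units not in (UNITS_HU, UNITS_BMD):
            raise ValueError(f"unknown unit tag {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.data.shape[axis]
        return (np.arange(n) + 0.5) * self.spacing[axis]

    def with_data(self, data: np.ndarray, units: str | None = None) -> "QCTImage":
        return replace(self, data=np.asarray(data, float),
                       units=self.units if units is None else units)

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine mapping voxel indices to mm (voxel-centre convention)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = np.asarray(self.spacing) * 0.5
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class SegmentationMask:
    """Binary voxel mask on the same grid conventions as :class:`QCTImage`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    #: "body" for vertebral-body-only masks, "whole" when posterior elements
    #: are part of the label
    scope: str = "body"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("SegmentationMask data must be 3D")
        self.spacing = _check_spacing(self.spacing)
        if self.scope not in ("body", "whole"):
            raise ValueError("scope must be 'body' or 'whole'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume

    def with_data(self, data: np.ndarray) -> "SegmentationMask":
        return replace(self, data=np.asarray(data).astype(bool))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = np.asarray(self.spacing) * 0.5
        return aff

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


def load_volume(path, units: str = UNITS_HU) -> QCTImage:
    """Read a NIfTI scalar volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return QCTImage(data, spacing, units=units)


def load_mask(path, scope: str = "body") -> SegmentationMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0.5
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegmentationMask(data, spacing, scope=scope)
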