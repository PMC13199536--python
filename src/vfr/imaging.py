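"""Virtual QCT scanner: HU rendering of phantoms with calibration rods.

The scanner maps true density to Hounsfield units through an affine law
``HU = a * rho_QCT + b``, applies an optional Gaussian point-spread blur and
additive Gaussian noise, and renders an in-line calibration phantom of five
cylindrical rods with known equivalent BMD (protocol values 0.00, 0.05,
0.10, 0.15, 0.20 g/cm^3; rod diameter 15 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import QCTImage, UNITS_HU
from .phantoms import VertebraPhantom

__all__ = ["ScannerModel", "RodLayout", "render_qct"]

#: protocol equivalent-BMD values of the five calibration rods, g/cm^3
ROD_BMD_VALUES = (0.00, 0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class RodLayout:
    """Placement of the five calibration rods (axes parallel to z)."""

    centers_xy: tuple[tuple[float, float], ...]   # mm, one per rod
    diameter: float                               # mm
    bmd_values: tuple[float, ...] = ROD_BMD_VALUES
    z_range: tuple[float, float] | None = None    # mm; None = full extent

    def __post_init__(self):
        if len(self.centers_xy) != len(self.bmd_values):
            raise ValueError("one centre per rod required")
        if len(self.bmd_values) != 5:
            raise ValueError("exactly 5 rods expected")
        if not all(b2 > b1 for b1, b2 in
                   zip(self.bmd_values, self.bmd_values[1:])):
            raise ValueError("rod BMD values must be strictly increasing")


@dataclass(frozen=True)
class ScannerModel:
    """Affine HU map plus blur/noise model and rod geometry."""

    hu_slope: float = 1000.0      # HU per g/cm^3
    hu_intercept: float = -15.0   # HU
    noise_sd: float = 0.0         # HU
    psf_sd_mm: float = 0.0        # Gaussian PSF sigma
    voxel_mm: float = 0.60
    rod_diameter: float = 15.0
    rod_gap: float = 5.0          # clearance between rods, mm
    rod_bmd: tuple[float, ...] = ROD_BMD_VALUES

    def __post_init__(self):
        if self.hu_slope <= 0:
            raise ValueError("hu_slope must be positive")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.psf_sd_mm < 0:
            raise ValueError("PSF sigma must be non-negative")

    @property
    def rod_row_extent(self) -> float:
        """Transverse length of the 5-rod row, mm."""
        n = len(self.rod_bmd)
        return n * self.rod_diameter + (n - 1) * self.rod_gap

    @property
    def rod_zone_mm(self) -> float:
        """Depth (y extent) to reserve for the rod row below the subject."""
        return self.rod_diameter + 6.0

    def default_rod_layout(self, grid_shape, spacing: float) -> RodLayout:
        """Rods in a row along x near the low-y edge of the volume."""
        lx = grid_shape[0] * spacing
        pitch = self.rod_diameter + self.rod_gap
        x0 = lx / 2 - self.rod_row_extent / 2 + self.rod_diameter / 2
        y = self.rod_diameter / 2 + 3.0
        centers = tuple((x0 + i * pitch, y) for i in range(len(self.rod_bmd)))
        return RodLayout(centers, self.rod_diameter, tuple(self.rod_bmd))


def render_qct(phantom: VertebraPhantom, scanner: ScannerModel,
               seed=None, layout: RodLayout | None = None) -> QCTImage:
    """Render a phantom to an HU volume with the calibration rods in frame.

    The noise-free, blur-free render satisfies ``HU = a * rho + b`` exactly
    at every voxel.  Reproducible: the same seed yields a bit-identical
    volume.  Raises if a rod would intersect the vertebra or leave the grid.
    """
    grid = phantom.grid
    sp = grid.spacing
    if layout is None:
        layout = scanner.default_rod_layout(grid.shape, sp)

    rho = phantom.density.data.copy()

    ax_x = (np.arange(grid.shape[0]) + 0.5) * sp
    ax_y = (np.arange(grid.shape[1]) + 0.5) * sp
    X, Y = np.meshgrid(ax_x, ax_y, indexing="ij")
    r = layout.diameter / 2

    zc = (np.arange(grid.shape[2]) + 0.5) * sp
    if layout.z_range is None:
        z_sel = np.ones(grid.shape[2], dtype=bool)
    else:
        z_sel = (zc >= layout.z_range[0]) & (zc <= layout.z_range[1])

    body = phantom.mask.data
    for (cx, cy), bmd in zip(layout.centers_xy, layout.bmd_values):
        if not (r <= cx <= grid.shape[0] * sp - r
                and r <= cy <= grid.shape[1] * sp - r):
            raise ValueError(f"rod at ({cx}, {cy}) leaves the volume")
        in_rod = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
        rod_vox = in_rod[:, :, None] & z_sel[None, None, :]
        if (rod_vox & body).any():
            raise ValueError("calibration rod intersects the vertebra")
        rho[rod_vox] = bmd

    hu = scanner.hu_slope * rho + scanner.hu_intercept
    if scanner.psf_sd_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=scanner.psf_sd_mm / sp)
    if scanner.noise_sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, scanner.noise_sd, size=hu.shape)

    meta = {
        "rod_centers_xy": layout.centers_xy,
        "rod_diameter": layout.diameter,
        "rod_bmd": layout.bmd_values,
        "hu_slope": scanner.hu_slope,
        "hu_intercept": scanner.hu_intercept,
    }
    return QCTImage(hu, (sp, sp, sp), units=UNITS_HU, meta=meta)
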