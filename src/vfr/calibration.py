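"""Densitometric calibration: HU to BMD via the in-line rod phantom.

The calibration fits ordinary least squares of the known equivalent BMD of
the five rods on the mean HU measured in a square-section prismatic region
of interest centred on each rod axis (side = half the rod diameter, 7.5 mm
at the 15 mm protocol diameter), then applies the fitted affine map
voxelwise.  Each scan is calibrated individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image import QCTImage, UNITS_BMD
from .imaging import RodLayout

__all__ = [
    "CalibrationModel",
    "DensitometricCalibration",
    "extract_rod_means",
    "fit_densitometric_calibration",
    "calibrate_image",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear HU -> BMD map for one scan."""

    slope: float            # g/cm^3 per HU
    intercept: float        # g/cm^3
    r_squared: float
    rod_mean_hu: tuple[float, ...]
    rod_bmd: tuple[float, ...]

    def __call__(self, hu):
        return self.slope * np.asarray(hu) + self.intercept


def rod_rois(image: QCTImage, layout: RodLayout, roi_side: float | None = None):
    """Boolean ROI volume per rod, in increasing-BMD order.

    The ROI is a square prism of side ``roi_side`` (default: half the rod
    diameter) centred on the rod axis, spanning the rod's full axial extent
    within the field of view.
    """
    side = layout.diameter / 2 if roi_side is None else roi_side
    half = side / 2
    sx, sy, sz = image.spacing
    cx_ax = image.voxel_centers_axis(0)
    cy_ax = image.voxel_centers_axis(1)
    cz_ax = image.voxel_centers_axis(2)
    if layout.z_range is None:
        z_sel = np.ones(image.shape[2], dtype=bool)
    else:
        z_sel = (cz_ax >= layout.z_range[0]) & (cz_ax <= layout.z_range[1])

    order = np.argsort(layout.bmd_values)
    rois = []
    for i in order:
        cx, cy = layout.centers_xy[i]
        if not (half <= cx <= image.shape[0] * sx - half
                and half <= cy <= image.shape[1] * sy - half):
            raise ValueError(f"ROI for rod at ({cx}, {cy}) exits the volume")
        in_x = np.abs(cx_ax - cx) <= half
        in_y = np.abs(cy_ax - cy) <= half
        roi = in_x[:, None, None] & in_y[None, :, None] & z_sel[None, None, :]
        if not roi.any():
            raise ValueError("empty rod ROI")
        rois.append(roi)
    return rois


def extract_rod_means(image: QCTImage, layout: RodLayout,
                      roi_side: float | None = None) -> np.ndarray:
    """Mean HU in each rod ROI, ordered by increasing rod BMD.

    Note: voxels of the phantom casing falling inside an ROI are *not*
    detected or excluded; ROIs are assumed to sample rod material only.
    """
    rois = rod_rois(image, layout, roi_side)
    return np.array([float(image.data[r].mean()) for r in rois])


def fit_densitometric_calibration(mean_hu, rod_bmd) -> CalibrationModel:
    """OLS of BMD on HU over the five rod observations."""
    hu = np.asarray(mean_hu, float)
    bmd = np.asarray(rod_bmd, float)
    if hu.shape != (5,) or bmd.shape != (5,):
        raise ValueError("exactly 5 paired rod observations required")
    if np.ptp(hu) == 0:
        raise ValueError("degenerate calibration: rod HU values all equal")
    if np.ptp(bmd) == 0:
        # zero-response edge case: flat map
        return CalibrationModel(0.0, float(bmd[0]), float("nan"),
                                tuple(hu), tuple(bmd))
    res = stats.linregress(hu, bmd)
    return CalibrationModel(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), tuple(hu), tuple(bmd))


def calibrate_image(image: QCTImage, model: CalibrationModel,
                    density_floor: float = 0.0) -> QCTImage:
    """Apply the fitted map voxelwise; clamps below ``density_floor``.

    Negative calibrated densities are physically meaningless (and the
    density-elasticity laws are undefined there), so values below the floor
    are clamped to it.  Raises if the image is already in g/cm^3.
    """
    if image.units == UNITS_BMD:
        raise ValueError("image already calibrated (units g/cm3)")
    bmd = np.maximum(model(image.data), density_floor)
    out = image.with_data(bmd, units=UNITS_BMD)
    out.meta = dict(image.meta, calibration={
        "slope": model.slope, "intercept": model.intercept,
        "r_squared": model.r_squared})
    return out


class DensitometricCalibration:
    """Scan-specific calibration as a fit/transform estimator.

    ``fit`` measures the rod ROIs and regresses BMD on HU; ``transform``
    converts an HU volume to a BMD volume.  Fitted state lives in
    ``model_`` (a :class:`CalibrationModel`).
    """

    def __init__(self, roi_side: float | None = None,
                 density_floor: float = 0.0):
        self.roi_side = roi_side
        self.density_floor = density_floor

    def fit(self, image: QCTImage, layout: RodLayout | None = None):
        if layout is None:
            layout = RodLayout(
                centers_xy=tuple(image.meta["rod_centers_xy"]),
                diameter=image.meta["rod_diameter"],
                bmd_values=tuple(image.meta["rod_bmd"]))
        mean_hu = extract_rod_means(image, layout, self.roi_side)
        bmd = np.sort(np.asarray(layout.bmd_values, float))
        self.model_ = fit_densitometric_calibration(mean_hu, bmd)
        self.layout_ = layout
        return self

    def transform(self, image: QCTImage) -> QCTImage:
        if not hasattr(self, "model_"):
            raise RuntimeError("calibration not fitted")
        return calibrate_image(image, self.model_, self.density_floor)

    def fit_transform(self, image: QCTImage,
                      layout: RodLayout | None = None) -> QCTImage:
        return self.fit(image, layout).transform(image)
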