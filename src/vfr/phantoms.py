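"""Analytic vertebra-like phantoms with known geometry and density.

The phantom is an elliptic cylinder (semi-axes ``a``, ``b`` mm, height ``h``
mm) with an optional cosine waist, emulating a vertebral body on a QCT grid.
Lytic lesions are ellipsoidal low-density inclusions strictly inside the
body.  Because the solid is analytic, ground truth is available for the
quantities the downstream pipeline estimates: the voxelised mask, the
density field rho_QCT(x), the six anatomical landmarks, the body height Hm
and the mean cross-sectional area (CSA).

Coordinates
-----------
World coordinates are mm; the body axis is z.  Landmarks and lesion centres
are specified in the *body frame* (origin at the body centre, axes aligned
with the grid before any tilt is applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image import QCTImage, SegmentationMask, UNITS_BMD

__all__ = [
    "PhantomGeometry",
    "Lesion",
    "GridSpec",
    "VertebraPhantom",
    "make_vertebra_phantom",
]


@dataclass(frozen=True)
class PhantomGeometry:
    """Parameters of the analytic vertebral-body solid.

    ``waist`` is the fractional in-plane radius reduction at mid-height
    (0 = straight cylinder); the in-plane scale is
    ``s(t) = 1 - waist * sin(pi t)**2`` for ``t`` in [0, 1] along the height,
    so both end cross-sections are the full ellipse.
    """

    a: float = 20.0          # transverse semi-axis, mm (left-right)
    b: float = 15.0          # sagittal semi-axis, mm (posterior-anterior)
    height: float = 30.0     # mm
    waist: float = 0.15
    tilt_deg: float = 0.0    # rotation about the x axis
    base_density: float = 0.15   # trabecular rho_QCT, g/cm^3
    posterior_elements: bool = False

    def __post_init__(self):
        if min(self.a, self.b, self.height) <= 0:
            raise ValueError("semi-axes and height must be positive")
        if not 0.0 <= self.waist < 1.0:
            raise ValueError("waist must be in [0, 1)")
        if self.base_density < 0:
            raise ValueError("base_density must be >= 0")

    def scale_at(self, t):
        """In-plane scale factor at normalised height t in [0, 1]."""
        return 1.0 - self.waist * np.sin(np.pi * np.clip(t, 0, 1)) ** 2


@dataclass(frozen=True)
class Lesion:
    """Ellipsoidal lytic lesion, centre in body-frame mm."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    multiplier: float = 0.0   # density multiplier in [0, 1)

    def __post_init__(self):
        if not 0.0 <= self.multiplier < 1.0:
            raise ValueError("lesion multiplier must be in [0, 1)")
        if min(self.radii) <= 0:
            raise ValueError("lesion radii must be positive")


@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int]
    spacing: float = 0.60     # mm, isotropic

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid shape too small")


def _rotation_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)


@dataclass
class VertebraPhantom:
    """Ground-truth phantom: analytic solid sampled on a voxel grid."""

    geometry: PhantomGeometry
    lesions: tuple[Lesion, ...]
    grid: GridSpec
    body_center: np.ndarray          # world mm
    mask: SegmentationMask           # vertebral-body scope
    density: QCTImage                # true rho_QCT field, g/cm^3
    landmarks: np.ndarray            # (6, 3) world mm; rows 0-2 superior
    hm_mm: float
    csa_mm2: float                   # analytic mean CSA (endplates excluded)
    meta: dict = field(default_factory=dict)

    # -- analytic ground truth ------------------------------------------------
    def analytic_volume_mm3(self) -> float:
        g = self.geometry
        t = np.linspace(0.0, 1.0, 20001)
        mean_s2 = float(np.trapezoid(g.scale_at(t) ** 2, t))
        return math.pi * g.a * g.b * g.height * mean_s2

    def analytic_bmc_g(self) -> float:
        """Analytic bone mineral content, g (density integrated over volume)."""
        g = self.geometry
        bmc = g.base_density * self.analytic_volume_mm3()
        for les in self.lesions:
            v = 4.0 / 3.0 * math.pi * float(np.prod(les.radii))
            bmc -= (1.0 - les.multiplier) * g.base_density * v
        return bmc / 1000.0   # mm^3 * g/cm^3 -> g

    def body_to_world(self, pts: np.ndarray) -> np.ndarray:
        R = _rotation_x(self.geometry.tilt_deg)
        return np.asarray(pts, float) @ R.T + self.body_center


def _auto_grid(geometry: PhantomGeometry, margin: float = 6.0,
               spacing: float = 0.60, rod_zone_mm: float = 0.0,
               min_xy_mm: float = 0.0) -> tuple[GridSpec, np.ndarray]:
    """Size a grid around the body, optionally reserving a rod zone at low y."""
    g = geometry
    tilt_pad = abs(math.sin(math.radians(g.tilt_deg))) * (g.b + g.height / 2)
    lx = max(2 * g.a + 2 * margin, min_xy_mm)
    ly = rod_zone_mm + 2 * g.b + 2 * margin + tilt_pad
    lz = g.height + 2 * margin + 2 * tilt_pad
    shape = tuple(int(np.ceil(l / spacing)) for l in (lx, ly, lz))
    center = np.array([lx / 2, rod_zone_mm + margin + g.b + tilt_pad / 2,
                       lz / 2])
    return GridSpec(shape, spacing), center


def make_vertebra_phantom(
    geometry: PhantomGeometry | None = None,
    lesions: tuple[Lesion, ...] = (),
    grid: GridSpec | None = None,
    body_center: np.ndarray | None = None,
    rod_zone_mm: float = 0.0,
    min_grid_xy_mm: float = 0.0,
    spacing: float = 0.60,
) -> VertebraPhantom:
    """Voxelise the analytic solid and its density field.

    When ``grid`` is omitted one is sized automatically around the body with
    a 6 mm margin; ``rod_zone_mm`` reserves space at low y for calibration
    rods and ``min_grid_xy_mm`` enforces a minimum transverse extent (so a
    full rod row fits).

    Raises
    ------
    ValueError
        If a lesion is not strictly inside the body, the body does not fit
        in the grid, or the grid is too coarse (< 10 voxels across the body).
    """
    g = geometry or PhantomGeometry()
    lesions = tuple(lesions)
    if grid is None:
        grid, auto_center = _auto_grid(g, spacing=spacing,
                                       rod_zone_mm=rod_zone_mm,
                                       min_xy_mm=min_grid_xy_mm)
        if body_center is None:
            body_center = auto_center
    if body_center is None:
        body_center = 0.5 * np.asarray(grid.shape) * grid.spacing
    body_center = np.asarray(body_center, float)

    if min(2 * g.a, 2 * g.b, g.height) / grid.spacing < 10:
        raise ValueError("grid too coarse: fewer than 10 voxels across body")

    def inside_body(pts_body: np.ndarray) -> np.ndarray:
        """Membership test in body-frame coordinates (vectorised)."""
        x, y, z = pts_body[..., 0], pts_body[..., 1], pts_body[..., 2]
        t = z / g.height + 0.5
        s = g.scale_at(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (x / (g.a * s)) ** 2 + (y / (g.b * s)) ** 2
        return (np.abs(z) <= g.height / 2) & (r2 <= 1.0)

    # lesion containment: centre and the 6 axis-extreme points must be
    # strictly inside (0.5 mm margin)
    for les in lesions:
        c = np.asarray(les.center, float)
        probes = [c]
        for ax in range(3):
            for sgn in (-1, 1):
                p = c.copy()
                p[ax] += sgn * (les.radii[ax] + 0.5)
                probes.append(p)
        if not inside_body(np.asarray(probes)).all():
            raise ValueError(f"lesion at {les.center} not strictly inside body")

    # voxel-centre sampling in the body frame
    sp = grid.spacing
    ax = [(np.arange(n) + 0.5) * sp for n in grid.shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) - body_center
    R = _rotation_x(g.tilt_deg)
    pts_body = pts @ R    # world -> body frame (R is orthogonal)

    mask = inside_body(pts_body)
    if not mask[1:-1, 1:-1, 1:-1].any() or mask[[0, -1], :, :].any() \
            or mask[:, [0, -1], :].any() or mask[:, :, [0, -1]].any():
        raise ValueError("body does not fit inside the grid")

    density = np.where(mask, g.base_density, 0.0)
    for les in lesions:
        d = (pts_body - np.asarray(les.center)) / np.asarray(les.radii)
        in_les = (d ** 2).sum(axis=-1) <= 1.0
        density = np.where(in_les & mask,
                           np.minimum(density, g.base_density * les.multiplier),
                           density)

    # analytic landmarks in body frame: most anterior point (+y) and the two
    # posterior corners at +/-120 deg from anterior, on each end cross-section
    zs, zi = g.height / 2, -g.height / 2
    lm_body = np.array([
        [0.0, g.b, zs],
        [-g.a * math.sqrt(3) / 2, -g.b / 2, zs],
        [g.a * math.sqrt(3) / 2, -g.b / 2, zs],
        [0.0, g.b, zi],
        [-g.a * math.sqrt(3) / 2, -g.b / 2, zi],
        [g.a * math.sqrt(3) / 2, -g.b / 2, zi],
    ])
    landmarks = lm_body @ R.T + body_center

    # analytic mean CSA excluding 10% endplate bands at each end
    f = 0.10
    t = np.linspace(f, 1 - f, 20001)
    csa = math.pi * g.a * g.b * float(np.trapezoid(g.scale_at(t) ** 2, t)) / (1 - 2 * f)

    return VertebraPhantom(
        geometry=g, lesions=lesions, grid=grid, body_center=body_center,
        mask=SegmentationMask(mask, (sp, sp, sp), scope="body"),
        density=QCTImage(density, (sp, sp, sp), units=UNITS_BMD),
        landmarks=landmarks, hm_mm=g.height, csa_mm2=csa,
    )
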