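"""Anatomical alignment: landmarks, endplate planes and the body frame.

Six virtual landmarks — the most anterior point and the right/left corners
of the posterior region, on both the superior and inferior endplates —
define a cranial and a caudal plane; their bisector plane becomes the model
transverse plane.  The model is rotated so the bisector normal is the z
axis, the projected anterior direction is +y, and the origin sits at the
centroid of the superior endplate.

Landmark placement is automated (the manual step of the clinical protocol
minimised this variability anyway): endplate surfaces are extracted as the
per-column extreme voxel faces of the mask, locally averaged over a 3x3
column neighbourhood to suppress voxelisation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import SegmentationMask
from .meshing import Tet10Mesh

__all__ = [
    "AnatomicalFrame",
    "place_landmarks",
    "align_to_anatomical_frame",
    "identify_endplate_nodes",
    "vertebral_height",
]


@dataclass
class AnatomicalFrame:
    """Rigid map from world to anatomical coordinates: x' = R (x - c) - t."""

    rotation: np.ndarray        # (3,3), rows are the anatomical axes
    center: np.ndarray          # world point mapped near the frame origin
    offset: np.ndarray          # residual translation after rotation
    cranial_plane: tuple[np.ndarray, np.ndarray]   # (point, normal), world
    caudal_plane: tuple[np.ndarray, np.ndarray]

    def to_anatomical(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return (pts - self.center) @ self.rotation.T - self.offset

    def to_world(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return (pts + self.offset) @ self.rotation + self.center


def _column_extreme_z(data: np.ndarray, spacing, top: bool):
    """Per-(x,y)-column extreme surface z (mm) and footprint validity."""
    any_col = data.any(axis=2)
    nz = data.shape[2]
    zidx = np.arange(nz)
    if top:
        k = np.where(data, zidx[None, None, :], -1).max(axis=2)
    else:
        k = np.where(data, zidx[None, None, :], nz).min(axis=2)
    z = (k + 0.5) * spacing[2]
    return np.where(any_col, z, np.nan), any_col


def _trimmed_plane(x, y, z, top: bool, band_mm: float = 0.8,
                   n_iter: int = 5):
    """LSQ endplate plane z = c0 + c1 x + c2 y with one-sided trimming.

    Columns over the side wall report extreme-z values far on the wrong
    side of the endplate (below a superior plane, above an inferior one);
    iterative rejection of those points leaves the true endplate columns.
    Returns (coefficients, inlier boolean mask).
    """
    keep = np.ones(len(z), bool)
    coeff = None
    for _ in range(n_iter):
        A = np.column_stack([np.ones(keep.sum()), x[keep], y[keep]])
        coeff, *_ = np.linalg.lstsq(A, z[keep], rcond=None)
        resid = z - (coeff[0] + coeff[1] * x + coeff[2] * y)
        new = resid > -band_mm if top else resid < band_mm
        if new.sum() < 4:
            break
        if np.array_equal(new, keep):
            break
        keep = new
    return coeff, keep


def _pick_landmarks(z_col, footprint, spacing, top: bool) -> np.ndarray:
    """Anterior point and posterior corners on one endplate surface."""
    ii, jj = np.nonzero(footprint)
    x = (ii + 0.5) * spacing[0]
    y = (jj + 0.5) * spacing[1]
    z = z_col[ii, jj]
    coeff, keep = _trimmed_plane(x, y, z, top)
    x, y = x[keep], y[keep]
    if x.size <= 3:
        raise ValueError("degenerate endplate: too few surface columns")
    cy = y.mean()

    def point(sel_idx) -> np.ndarray:
        # virtual landmark on the identified endplate plane
        xs, ys = x[sel_idx], y[sel_idx]
        return np.array([xs, ys, coeff[0] + coeff[1] * xs + coeff[2] * ys])

    # anterior: maximum y; among ties the column nearest the x centroid
    cand = np.flatnonzero(y >= y.max() - spacing[1] / 2)
    anterior = point(cand[np.argmin(np.abs(x[cand] - x.mean()))])

    # posterior corners: x extremes among the posterior half of the footprint
    post = np.flatnonzero(y < cy)
    if post.size < 2:
        raise ValueError("degenerate endplate: posterior region too small")
    left = point(post[np.argmin(x[post])])
    right = point(post[np.argmax(x[post])])
    return np.stack([anterior, left, right])


def place_landmarks(mask: SegmentationMask) -> np.ndarray:
    """Six landmarks, rows 0-2 on the superior endplate, 3-5 inferior.

    Row order per endplate: anterior, posterior-left, posterior-right.
    Landmarks are virtual: placed on the trimmed least-squares endplate
    plane at the chosen footprint columns.  Assumes the body axis is
    roughly grid-aligned (guaranteed for the synthetic phantoms; tilts of
    a few degrees are fine).
    """
    data = mask.data
    if data.sum() <= 3:
        raise ValueError("degenerate mask: too few voxels for landmarks")
    z_top, fp = _column_extreme_z(data, mask.spacing, top=True)
    z_bot, _ = _column_extreme_z(data, mask.spacing, top=False)
    sup = _pick_landmarks(z_top, fp, mask.spacing, top=True)
    inf = _pick_landmarks(z_bot, fp, mask.spacing, top=False)
    return np.vstack([sup, inf])


def _plane(points3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plane through three points, normal oriented toward +z."""
    p = np.asarray(points3, float)
    n = np.cross(p[1] - p[0], p[2] - p[0])
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("collinear landmark triple")
    n = n / norm
    if n[2] < 0:
        n = -n
    return p.mean(axis=0), n


def align_to_anatomical_frame(mesh: Tet10Mesh, landmarks: np.ndarray
                              ) -> tuple[AnatomicalFrame, Tet10Mesh]:
    """Rotate the mesh so the endplate bisector plane is transverse.

    Builds cranial and caudal planes from the two landmark triples, takes
    the bisector normal as the anatomical z axis and the projected anterior
    direction as +y, then places the origin at the centroid of the superior
    endplate (the node band within one element size of the top).
    """
    landmarks = np.asarray(landmarks, float)
    if landmarks.shape != (6, 3):
        raise ValueError("six landmarks required")
    c_cr, n_cr = _plane(landmarks[:3])
    c_ca, n_ca = _plane(landmarks[3:])
    z_ax = n_cr + n_ca
    z_ax = z_ax / np.linalg.norm(z_ax)

    anterior = landmarks[0] - 0.5 * (landmarks[1] + landmarks[2])
    y_ax = anterior - (anterior @ z_ax) * z_ax
    ny = np.linalg.norm(y_ax)
    if ny < 1e-9:
        raise ValueError("anterior direction parallel to axial axis")
    y_ax = y_ax / ny
    x_ax = np.cross(y_ax, z_ax)
    rot = np.stack([x_ax, y_ax, z_ax])            # rows = axes

    center = landmarks.mean(axis=0)
    rotated = (mesh.nodes - center) @ rot.T
    zmax = rotated[:, 2].max()
    band = rotated[:, 2] >= zmax - mesh.elem_size
    offset = rotated[band].mean(axis=0)
    offset[2] = zmax                    # origin exactly on the top surface
    frame = AnatomicalFrame(rotation=rot, center=center, offset=offset,
                            cranial_plane=(c_cr, n_cr),
                            caudal_plane=(c_ca, n_ca))
    aligned = Tet10Mesh(rotated - offset, mesh.elems.copy(),
                        mesh.elem_size, mesh.n_cubes)
    return frame, aligned


def identify_endplate_nodes(mesh: Tet10Mesh, band_mm: float = 1.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Node indices within ``band_mm`` of the extreme axial levels."""
    if band_mm <= 0:
        raise ValueError("band must be positive")
    z = mesh.nodes[:, 2]
    cranial = np.flatnonzero(z >= z.max() - band_mm)
    caudal = np.flatnonzero(z <= z.min() + band_mm)
    if cranial.size == 0 or caudal.size == 0:
        raise ValueError("empty endplate band")
    if np.intersect1d(cranial, caudal).size:
        raise ValueError("endplate bands overlap: band too large for body")
    return cranial, caudal


def vertebral_height(mesh: Tet10Mesh, cranial: np.ndarray,
                     caudal: np.ndarray) -> float:
    """Hm: axial distance between the endplate node-set centroids, mm."""
    if cranial.size == 0 or caudal.size == 0:
        raise ValueError("empty endplate node set")
    return float(abs(mesh.nodes[cranial, 2].mean()
                     - mesh.nodes[caudal, 2].mean()))
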