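"""Structured quadratic tetrahedral meshing of binary masks.

The mask is resampled onto a cubic lattice of edge ``elem_size`` (a cube is
kept when its centre falls inside the mask), each kept cube is split into
six tetrahedra by the Kuhn (path) triangulation — which is conforming
across neighbouring cubes — and the linear tets are promoted to 10-node
quadratic tets (TET10/C3D10) by inserting shared edge-midpoint nodes.

Because midside nodes sit exactly at edge midpoints, the geometry map of
every element is affine: Jacobians are constant per element and positive by
construction, and the mesh volume equals the kept-cube volume exactly.

TET10 node ordering follows the Abaqus C3D10 convention: corners 1-4, then
midpoints of edges (1,2), (2,3), (3,1), (1,4), (2,4), (3,4).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .image import SegmentationMask

__all__ = ["Tet10Mesh", "mask_to_tet10_mesh", "TET10_EDGES"]

#: local corner pairs defining the six midside nodes, C3D10 order
TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))

_AXIS_UNIT = np.eye(3, dtype=np.int64)


def _kuhn_tets() -> np.ndarray:
    """Six corner-offset tuples (4 corners x 3 lattice offsets each).

    Each tet follows a monotone path from cube corner (0,0,0) to (1,1,1);
    odd permutations have their 2nd/3rd vertices swapped so all signed
    volumes are positive.
    """
    tets = []
    for perm in permutations(range(3)):
        c0 = np.zeros(3, dtype=np.int64)
        c1 = c0 + _AXIS_UNIT[perm[0]]
        c2 = c1 + _AXIS_UNIT[perm[1]]
        c3 = c2 + _AXIS_UNIT[perm[2]]
        sign = np.linalg.det(_AXIS_UNIT[list(perm)])
        tets.append([c0, c1, c2, c3] if sign > 0 else [c0, c2, c1, c3])
    return np.asarray(tets)           # (6, 4, 3)


_KUHN = _kuhn_tets()


@dataclass
class Tet10Mesh:
    nodes: np.ndarray        # (n_nodes, 3) mm
    elems: np.ndarray        # (n_elems, 10) int
    elem_size: float         # cube edge, mm
    n_cubes: int

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def corner_coords(self) -> np.ndarray:
        """(n_elems, 4, 3) corner coordinates."""
        return self.nodes[self.elems[:, :4]]

    def signed_volumes(self) -> np.ndarray:
        x = self.corner_coords()
        v = x[:, 1:] - x[:, :1]
        return np.linalg.det(v) / 6.0

    def volume(self) -> float:
        return float(self.signed_volumes().sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "Tet10Mesh":
        """Rigidly transformed copy: x' = R @ x + t."""
        nodes = self.nodes @ np.asarray(rotation).T + np.asarray(translation)
        return Tet10Mesh(nodes, self.elems.copy(), self.elem_size,
                         self.n_cubes)


def mask_to_tet10_mesh(mask: SegmentationMask,
                       elem_size: float = 1.0) -> Tet10Mesh:
    """Mesh a binary mask with TET10 elements of cube edge ``elem_size`` mm.

    Raises on an empty mask or when ``elem_size`` is below the voxel
    spacing (the cube sampling would alias).
    """
    data = mask.data
    if not data.any():
        raise ValueError("cannot mesh an empty mask")
    sp = np.asarray(mask.spacing, float)
    h = float(elem_size)
    if h < sp.min() - 1e-12:
        raise ValueError("elem_size must be >= voxel spacing")

    idx = np.argwhere(data)
    bb_min = idx.min(axis=0) * sp                 # world corner of bbox
    bb_max = (idx.max(axis=0) + 1) * sp
    n_cubes_axis = np.maximum(np.ceil((bb_max - bb_min) / h - 1e-9), 1).astype(int)

    # cube centres -> containing voxel -> keep where mask is set
    ranges = [np.arange(n) for n in n_cubes_axis]
    ci, cj, ck = np.meshgrid(*ranges, indexing="ij")
    cubes = np.stack([ci, cj, ck], axis=-1).reshape(-1, 3)
    centers = bb_min + (cubes + 0.5) * h
    vox = np.floor(centers / sp).astype(int)
    in_grid = np.all((vox >= 0) & (vox < np.asarray(data.shape)), axis=1)
    keep = np.zeros(len(cubes), dtype=bool)
    vg = vox[in_grid]
    keep[in_grid] = data[vg[:, 0], vg[:, 1], vg[:, 2]]
    cubes = cubes[keep]
    if len(cubes) == 0:
        raise ValueError("no element cube centre falls inside the mask")

    # global corner lattice keys, (n_cubes, 6 tets, 4 corners)
    lat_shape = n_cubes_axis + 1
    corners = cubes[:, None, None, :] + _KUHN[None, :, :, :]    # (nc,6,4,3)
    keys = (corners[..., 0] * lat_shape[1] + corners[..., 1]) \
        * lat_shape[2] + corners[..., 2]
    keys = keys.reshape(-1, 4)                                   # (ntet, 4)

    uniq_corner, corner_id = np.unique(keys, return_inverse=True)
    corner_id = corner_id.reshape(-1, 4)
    # decode lattice coordinates of unique corners
    k = uniq_corner % lat_shape[2]
    rem = uniq_corner // lat_shape[2]
    j = rem % lat_shape[1]
    i = rem // lat_shape[1]
    corner_xyz = bb_min + np.stack([i, j, k], axis=-1) * h

    # shared midside nodes keyed by the unordered corner pair
    edge_pairs = np.stack(
        [np.sort(np.stack([keys[:, e0], keys[:, e1]], axis=-1), axis=-1)
         for e0, e1 in TET10_EDGES], axis=1)                     # (ntet,6,2)
    edge_keys = edge_pairs[..., 0] * (uniq_corner.max() + 1) + edge_pairs[..., 1]
    uniq_edge, edge_id = np.unique(edge_keys, return_inverse=True)
    edge_id = edge_id.reshape(-1, 6)
    e_hi = uniq_edge % (uniq_corner.max() + 1)
    e_lo = uniq_edge // (uniq_corner.max() + 1)
    # midside coordinates = midpoint of the two corner coordinates
    lo_idx = np.searchsorted(uniq_corner, e_lo)
    hi_idx = np.searchsorted(uniq_corner, e_hi)
    mid_xyz = 0.5 * (corner_xyz[lo_idx] + corner_xyz[hi_idx])

    nodes = np.vstack([corner_xyz, mid_xyz])
    elems = np.hstack([corner_id, edge_id + len(uniq_corner)]).astype(np.int64)

    mesh = Tet10Mesh(nodes=nodes, elems=elems, elem_size=h,
                     n_cubes=len(cubes))
    if (mesh.signed_volumes() <= 0).any():
        raise RuntimeError("non-positive element Jacobian in structured mesh")
    return mesh
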