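"""Plain-text exporters: Abaqus INP and legacy-VTK mesh/result files.

Connectivity ordering is written exactly as stored (C3D10: corners 1-4 then
edge midpoints (1,2), (2,3), (3,1), (1,4), (2,4), (3,4)).  VTK's quadratic
tetra (cell type 24) lists the same six midside nodes — its third midside
is edge (0,2), the identical node to C3D10's (2,0) — so both formats share
one connectivity row and no permutation is applied.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import Tet10Mesh
from .model import FEModel

__all__ = ["write_inp", "write_vtk_mesh", "write_vtk_point_data"]


def write_inp(model: FEModel, path) -> None:
    """Abaqus input deck: nodes, C3D10 elements, per-element materials."""
    mesh = model.mesh
    lines = ["*HEADING", "vfr vertebral body model", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.6f}, {y:.6f}, {z:.6f}")
    lines.append("*ELEMENT, TYPE=C3D10")
    for e, conn in enumerate(mesh.elems, start=1):
        ids = ", ".join(str(c + 1) for c in conn)
        lines.append(f"{e}, {ids}")
    E = model.materials.E
    sy = model.materials.sigma_y
    epy = model.materials.E_py
    nu = model.nu
    for e in range(mesh.n_elems):
        lines.append(f"*SOLID SECTION, ELSET=EL{e + 1}, MATERIAL=MAT{e + 1}")
        lines.append(f"*ELSET, ELSET=EL{e + 1}")
        lines.append(str(e + 1))
        lines.append(f"*MATERIAL, NAME=MAT{e + 1}")
        lines.append("*ELASTIC")
        lines.append(f"{E[e]:.6g}, {nu}")
        lines.append("*PLASTIC")
        # bilinear hardening: yield point and a far post-yield point
        eps_far = 0.5
        lines.append(f"{sy[e]:.6g}, 0.0")
        lines.append(f"{sy[e] + epy[e] * eps_far:.6g}, {eps_far}")
    for name, nodes in (("CRANIAL", model.cranial_nodes),
                        ("CAUDAL", model.caudal_nodes)):
        lines.append(f"*NSET, NSET={name}")
        for chunk in np.array_split(nodes + 1, max(1, len(nodes) // 8)):
            lines.append(", ".join(map(str, chunk)))
    Path(path).write_text("\n".join(lines) + "\n")


def _vtk_header(mesh: Tet10Mesh) -> list[str]:
    lines = ["# vtk DataFile Version 3.0", "vfr mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elems} {mesh.n_elems * 11}")
    lines += ["10 " + " ".join(map(str, row)) for row in mesh.elems]
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines += ["24"] * mesh.n_elems
    return lines


def write_vtk_mesh(mesh: Tet10Mesh, path,
                   cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy-VTK unstructured grid with optional per-element scalars."""
    lines = _vtk_header(mesh)
    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elems}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in np.asarray(arr, float)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_point_data(mesh: Tet10Mesh, path,
                         vectors: dict[str, np.ndarray] | None = None,
                         scalars: dict[str, np.ndarray] | None = None) -> None:
    """Legacy-VTK result file: nodal vectors (displacement) and scalars."""
    lines = _vtk_header(mesh)
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    for name, arr in (vectors or {}).items():
        lines.append(f"VECTORS {name} double")
        lines += [f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}"
                  for v in np.asarray(arr, float)]
    for name, arr in (scalars or {}).items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in np.asarray(arr, float)]
    Path(path).write_text("\n".join(lines) + "\n")
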