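"""Minimal legacy-VTK (ASCII unstructured grid) export for meshes and fields.

Writes hexahedra (cell type 12) and trusses (cell type 3) with region tags
as cell data; node sets, displacements and nodal von Mises as point data.
Readable by ParaView and VTK-based tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .fem import SolutionField, nodal_von_mises
from .geometry import Mesh

__all__ = ["write_vtk_mesh", "write_vtk_solution"]


def _header(fh, n_nodes, nodes):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write("spinefem L4/5 motion segment\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    fh.write(f"POINTS {n_nodes} double\n")
    for p in nodes:
        fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def _cells(fh, mesh: Mesh):
    n_hex = len(mesh.hexes)
    n_tr = len(mesh.trusses)
    total = n_hex + n_tr
    size = n_hex * 9 + n_tr * 3
    fh.write(f"CELLS {total} {size}\n")
    for h in mesh.hexes:
        fh.write("8 " + " ".join(map(str, h)) + "\n")
    for t in mesh.trusses:
        fh.write(f"2 {t[0]} {t[1]}\n")
    fh.write(f"CELL_TYPES {total}\n")
    fh.write("12\n" * n_hex)
    fh.write("3\n" * n_tr)


def _cell_scalars(fh, name, values, fmt="%d"):
    fh.write(f"SCALARS {name} {'int' if fmt == '%d' else 'double'} 1\n")
    fh.write("LOOKUP_TABLE default\n")
    for v in values:
        fh.write((fmt % v) + "\n")


def write_vtk_mesh(path: str | Path, mesh: Mesh) -> None:
    """Mesh with region ids and node-set membership masks."""
    with open(path, "w") as fh:
        _header(fh, mesh.n_nodes, mesh.nodes)
        _cells(fh, mesh)
        fh.write(f"CELL_DATA {len(mesh.hexes) + len(mesh.trusses)}\n")
        _cell_scalars(
            fh, "region", np.concatenate([mesh.hex_region, mesh.truss_region])
        )
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        mask = np.zeros(mesh.n_nodes, dtype=int)
        for i, (name, ids) in enumerate(sorted(mesh.node_sets.items()), start=1):
            mask[ids] = i
        _cell_scalars(fh, "node_set", mask)


def write_vtk_solution(
    path: str | Path, mesh: Mesh, solution: SolutionField
) -> None:
    """Solution field: displacements, nodal von Mises, region and activity."""
    with open(path, "w") as fh:
        _header(fh, mesh.n_nodes, mesh.nodes)
        _cells(fh, mesh)
        n_cells = len(mesh.hexes) + len(mesh.trusses)
        fh.write(f"CELL_DATA {n_cells}\n")
        _cell_scalars(
            fh, "region", np.concatenate([mesh.hex_region, mesh.truss_region])
        )
        _cell_scalars(
            fh,
            "von_mises",
            np.concatenate([solution.element_vm, np.zeros(len(mesh.trusses))]),
            fmt="%.9g",
        )
        _cell_scalars(
            fh,
            "active",
            np.concatenate(
                [solution.hex_active.astype(int), solution.truss_active.astype(int)]
            ),
        )
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("VECTORS displacement double\n")
        for d in solution.u:
            fh.write(f"{d[0]:.9g} {d[1]:.9g} {d[2]:.9g}\n")
        _cell_scalars(
            fh, "nodal_von_mises", nodal_von_mises(mesh, solution), fmt="%.9g"
        )
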