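"""Minimal legacy-ASCII VTK writers for grids, maps and tet meshes.

Writes the subset of the legacy VTK format needed to inspect tissue
grids (STRUCTURED_POINTS with cell data), nodal maps (point data) and
tetrahedral torso meshes (UNSTRUCTURED_GRID) in ParaView.
"""

from __future__ import annotations

import numpy as np


def _header(f, title):
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")


def _write_array(f, name, values):
    values = np.asarray(values)
    if values.ndim == 1:
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, values.reshape(-1, 1), fmt="%.6g")
    elif values.ndim == 2 and values.shape[1] == 3:
        f.write(f"VECTORS {name} float\n")
        np.savetxt(f, values, fmt="%.6g")
    else:
        raise ValueError(f"unsupported array shape {values.shape} for {name}")


def write_grid_vtk(grid, path, cell_data: dict | None = None,
                   point_data: dict | None = None):
    """Write a TissueGrid as legacy STRUCTURED_POINTS.

    Default cell data: label, layer, sigma_l, sigma_t and the fiber
    field; extra arrays may be passed in ``cell_data`` (per element, any
    shape broadcastable to the grid) or ``point_data`` (per node).
    """
    nx, ny, nz = grid.shape
    data = {
        "label": grid.label,
        "layer": grid.layer,
        "sigma_l": grid.sigma_l,
        "sigma_t": grid.sigma_t,
        "fiber": grid.fiber,
    }
    data.update(cell_data or {})
    with open(path, "w") as f:
        _header(f, "ivtlab tissue grid")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write(f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}\n")
        f.write(f"SPACING {grid.dx} {grid.dx} {grid.dx}\n")
        f.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, values in data.items():
            arr = np.asarray(values)
            if arr.ndim == 4:  # vector field (nx, ny, nz, 3)
                flat = arr.reshape(-1, 3, order="F")
                _write_array(f, name, flat)
            else:
                _write_array(f, name, arr.ravel(order="F").astype(float))
        if point_data:
            f.write(f"POINT_DATA {(nx + 1) * (ny + 1) * (nz + 1)}\n")
            for name, values in point_data.items():
                _write_array(f, name, np.asarray(values).ravel(order="F"))


def write_tet_mesh_vtk(mesh, path, point_data: dict | None = None):
    """Write a TorsoVolume as a legacy UNSTRUCTURED_GRID with cell sigma."""
    nodes, tets = mesh.nodes, mesh.tets
    with open(path, "w") as f:
        _header(f, "ivtlab torso mesh")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {nodes.shape[0]} float\n")
        np.savetxt(f, nodes, fmt="%.6g")
        m = tets.shape[0]
        f.write(f"CELLS {m} {5 * m}\n")
        cells = np.hstack([np.full((m, 1), 4, dtype=np.int64), tets])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 10, dtype=np.int64), fmt="%d")  # VTK_TETRA
        f.write(f"CELL_DATA {m}\n")
        _write_array(f, "sigma", mesh.sigma)
        if mesh.region is not None:
            _write_array(f, "region", mesh.region.astype(float))
        if point_data:
            f.write(f"POINT_DATA {nodes.shape[0]}\n")
            for name, values in point_data.items():
                _write_array(f, name, np.asarray(values))
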