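"""Export of meshes, fields and traces.

Meshes and attached fields are written as legacy-VTK ASCII unstructured
grids (readable by ParaView/VTK); time series as one file per snapshot plus
a ``.series`` JSON index.  Probe traces and metrics go to CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .meshing import Mesh
from .monodomain import FieldSeries

__all__ = ["write_vtk", "write_vtk_series", "save_field_series", "load_field_series"]

_VTK_CELL_TYPE = {1: 3, 2: 5, 3: 10}  # line, triangle, tetra


def write_vtk(
    mesh: Mesh,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write the mesh (with optional nodal/cell fields) as legacy VTK ASCII.

    Compartment labels are always attached as cell data ``compartment``.
    """
    path = Path(path)
    pts3 = np.zeros((mesh.num_nodes, 3))
    pts3[:, : mesh.points.shape[1]] = mesh.points
    cells = mesh.cells
    npts_per = cells.shape[1]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nuterosim mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.num_nodes} double\n")
        np.savetxt(f, pts3, fmt="%.10g")
        f.write(f"CELLS {mesh.num_cells} {mesh.num_cells * (npts_per + 1)}\n")
        np.savetxt(
            f,
            np.column_stack([np.full(mesh.num_cells, npts_per), cells]),
            fmt="%d",
        )
        f.write(f"CELL_TYPES {mesh.num_cells}\n")
        np.savetxt(
            f, np.full(mesh.num_cells, _VTK_CELL_TYPE[mesh.dim]), fmt="%d"
        )

        cell_data = dict(cell_data or {})
        cell_data.setdefault("compartment", mesh.cell_labels)
        f.write(f"CELL_DATA {mesh.num_cells}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.10g" if kind == "double" else "%d")
            else:
                vec = np.zeros((len(arr), 3))
                vec[:, : arr.shape[1]] = arr
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, vec, fmt="%.10g")

        if point_data:
            f.write(f"POINT_DATA {mesh.num_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.10g")
                else:
                    vec = np.zeros((len(arr), 3))
                    vec[:, : arr.shape[1]] = arr
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, vec, fmt="%.10g")


def write_vtk_series(series: FieldSeries, outdir, basename: str) -> Path:
    """One VTK file per snapshot plus a ParaView ``.series`` index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    point = series.values.ndim == 2 and series.values.shape[1] == series.mesh.num_nodes
    for i, t in enumerate(series.times):
        name = f"{basename}_{i:05d}.vtk"
        data = {series.name: series.values[i]}
        write_vtk(
            series.mesh,
            outdir / name,
            point_data=data if point else None,
            cell_data=None if point else data,
        )
        files.append({"name": name, "time": float(t)})
    index = outdir / f"{basename}.vtk.series"
    index.write_text(json.dumps({"file-series-version": "1.0", "files": files}, indent=1))
    return index


def save_field_series(series: FieldSeries, path) -> None:
    """Compact binary save (npz) of a field series for pipeline hand-off."""
    np.savez_compressed(
        path,
        times=series.times,
        values=series.values,
        name=np.array(series.name),
        units=np.array(series.units),
        points=series.mesh.points,
        cells=series.mesh.cells,
        cell_labels=series.mesh.cell_labels,
        facets=series.mesh.facets,
        facet_labels=series.mesh.facet_labels,
        dim=np.array(series.mesh.dim),
    )


def load_field_series(path) -> FieldSeries:
    z = np.load(path, allow_pickle=False)
    mesh = Mesh(
        dim=int(z["dim"]),
        points=z["points"],
        cells=z["cells"],
        cell_labels=z["cell_labels"],
        facets=z["facets"],
        facet_labels=z["facet_labels"],
    )
    return FieldSeries(
        mesh, z["times"], z["values"], str(z["name"]), str(z["units"])
    )
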