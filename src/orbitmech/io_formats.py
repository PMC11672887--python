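"""Plain-text mesh and field writers (VTU, STL) for external visualization.

The VTU writer emits minimal ASCII VTK XML UnstructuredGrid files —
tetrahedra (cell type 10) with optional per-point vector/scalar data —
readable by ParaView and VTK.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import TissueMesh

__all__ = ["write_vtu", "write_vtu_series"]


def _data_array(name: str, data: np.ndarray, ncomp: int) -> str:
    flat = np.asarray(data, dtype=float).reshape(-1)
    body = " ".join(f"{v:.9g}" for v in flat)
    return (
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>'
    )


def write_vtu(
    path,
    mesh: TissueMesh,
    nodes: np.ndarray | None = None,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write the tet mesh (optionally with displaced nodes) as ASCII VTU."""
    X = mesh.nodes if nodes is None else np.asarray(nodes)
    tets = mesh.tets
    npts, ncell = len(X), len(tets)
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncell}">',
        "<Points>",
        _data_array("Points", X, 3),
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">'
        + " ".join(map(str, tets.reshape(-1)))
        + "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">'
        + " ".join(str(4 * (i + 1)) for i in range(ncell))
        + "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">'
        + " ".join(["10"] * ncell)
        + "</DataArray>",
        "</Cells>",
    ]
    pd_items = dict(point_data or {})
    if pd_items:
        parts.append("<PointData>")
        for name, arr in pd_items.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(_data_array(name, arr, ncomp))
        parts.append("</PointData>")
    cd_items = dict(cell_data or {})
    cd_items.setdefault("tissue", mesh.tet_label.astype(float))
    parts.append("<CellData>")
    for name, arr in cd_items.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        parts.append(_data_array(name, arr, ncomp))
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def write_vtu_series(prefix, mesh: TissueMesh, fields: list) -> list:
    """Write one VTU per incremental step; returns the written paths."""
    paths = []
    for k, u in enumerate(fields):
        p = Path(f"{prefix}_{k:03d}.vtu")
        write_vtu(p, mesh, nodes=mesh.nodes + u, point_data={"displacement": u})
        paths.append(p)
    return paths
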