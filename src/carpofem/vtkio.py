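"""Minimal VTU (VTK XML unstructured grid) and CSV mesh output.

ASCII VTU is written directly — the files carry only points, cells and
integer/float cell-data arrays, which covers everything a stress viewer
(ParaView and friends) needs from this package.  A matching reader is
provided for round-trip checks and for regenerating reports from stored
fields.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["write_vtu", "read_vtu", "write_mesh_csv"]

_VTK_TYPE = {"tetra": 10, "triangle": 5}
_VTK_NPTS = {10: 4, 5: 3}


def _fmt(a: np.ndarray) -> str:
    if np.issubdtype(a.dtype, np.integer):
        return " ".join(str(int(x)) for x in a.ravel())
    return " ".join(format(float(x), ".17g") for x in a.ravel())


def write_vtu(
    path,
    points: np.ndarray,
    cells: Sequence[Tuple[str, np.ndarray]],
    cell_data: Dict[str, np.ndarray] | None = None,
) -> None:
    """Write an ASCII .vtu file.

    ``cells`` is a sequence of (cell_type, connectivity) blocks with
    cell_type in {"tetra", "triangle"}; cell-data arrays must match the
    total cell count in block order.
    """
    path = Path(path)
    if path.suffix != ".vtu":
        raise ValueError(f"expected a .vtu path, got {path.name!r}")
    conn, types, offsets = [], [], []
    off = 0
    for kind, block in cells:
        t = _VTK_TYPE[kind]
        block = np.asarray(block)
        conn.append(block.ravel())
        types.append(np.full(len(block), t, dtype=np.int64))
        off_block = off + np.cumsum(np.full(len(block), _VTK_NPTS[t]))
        offsets.append(off_block)
        off = off_block[-1] if len(block) else off
    conn = np.concatenate(conn) if conn else np.array([], dtype=np.int64)
    types = np.concatenate(types)
    offsets = np.concatenate(offsets)
    n_cells = len(types)
    cell_data = cell_data or {}
    for name, arr in cell_data.items():
        if len(arr) != n_cells:
            raise ValueError(
                f"cell data {name!r} has {len(arr)} entries for {n_cells} cells"
            )

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(points)}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(np.asarray(points, dtype=float)),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(conn),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(offsets),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt(types),
        "</DataArray>",
        "</Cells>",
        "<CellData>",
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        vtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        lines.append(f'<DataArray type="{vtype}" Name="{name}" format="ascii">')
        lines.append(_fmt(arr))
        lines.append("</DataArray>")
    lines += ["</CellData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(lines))


def read_vtu(path):
    """Read points, cell blocks and cell data from an ASCII .vtu file."""
    path = Path(path)
    root = ET.parse(path).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path} is not an unstructured-grid VTU file")

    def arr(elem, dtype):
        return np.array(elem.text.split(), dtype=dtype)

    pts = arr(piece.find("./Points/DataArray"), float).reshape(-1, 3)
    cells_el = {e.get("Name"): e for e in piece.findall("./Cells/DataArray")}
    conn = arr(cells_el["connectivity"], np.int64)
    offsets = arr(cells_el["offsets"], np.int64)
    types = arr(cells_el["types"], np.int64)
    cells: List[Tuple[str, np.ndarray]] = []
    start = 0
    for t in (10, 5):  # report tets first, then triangles
        sel = types == t
        if not np.any(sel):
            continue
        block = []
        for i in np.flatnonzero(sel):
            s = offsets[i - 1] if i > 0 else 0
            block.append(conn[s : offsets[i]])
        name = "tetra" if t == 10 else "triangle"
        cells.append((name, np.array(block)))
    cell_data = {}
    for e in piece.findall("./CellData/DataArray"):
        dtype = np.int64 if e.get("type") == "Int64" else float
        cell_data[e.get("Name")] = arr(e, dtype)
    return pts, cells, cell_data


def write_mesh_csv(path, mesh) -> None:
    """Plain-text node/element dump of a labelled mesh (for diffing)."""
    import pandas as pd

    path = Path(path)
    nodes = pd.DataFrame(mesh.nodes, columns=["x", "y", "z"])
    nodes["body"] = mesh.node_body
    tets = pd.DataFrame(mesh.tets, columns=["n0", "n1", "n2", "n3"])
    tets["body"] = mesh.tet_body
    tris = pd.DataFrame(mesh.tris, columns=["n0", "n1", "n2"])
    tris["body"] = mesh.tri_body
    tris["region"] = mesh.tri_region
    with open(path, "w") as fh:
        fh.write(f"# variant={mesh.variant} bodies={','.join(mesh.body_names)}\n")
        fh.write("# nodes\n")
        nodes.to_csv(fh, index=False)
        fh.write("# tets\n")
        tets.to_csv(fh, index=False)
        fh.write("# triangles\n")
        tris.to_csv(fh, index=False)
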