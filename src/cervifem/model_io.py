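"""Model file formats.

VTU (ASCII XML UnstructuredGrid) is the lossless interchange format: nodes,
element blocks, named node/element sets and surface patches (encoded as
FieldData integer arrays ``ns:``/``es:``/``sf:``), material cell data and
arbitrary point/cell result fields all round-trip.  Legacy ``.vtk`` is a
write-only mesh export, and ``.inp`` writes the Abaqus keyword subset
(*NODE, *ELEMENT, *NSET, *ELSET, *SURFACE) for cross-checking in external
solvers.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .fem import Model
from .mesh import ElementBlock, Mesh

VTK_TYPE = {"truss2": 3, "tet4": 10, "hex8": 12, "wedge6": 13, "tet10": 24, "wedge15": 26}
KIND_OF_VTK = {v: k for k, v in VTK_TYPE.items()}
INP_TYPE = {"tet4": "C3D4", "tet10": "C3D10M", "wedge6": "C3D6",
            "wedge15": "C3D15", "truss2": "T3D2", "hex8": "C3D8"}

# Abaqus face numbering of a tet (S1..S4) against our local face order
INP_TET_FACE = {0: "S1", 1: "S2", 2: "S3", 3: "S4"}


class FormatError(ValueError):
    """Unknown extension or malformed file content."""


# ----------------------------------------------------------------------
# VTU


def _fmt_array(a: np.ndarray) -> str:
    flat = np.asarray(a).ravel()
    if flat.dtype.kind == "f":
        return " ".join(repr(float(v)) for v in flat)
    return " ".join(str(int(v)) for v in flat)


def _data_array(parent, name, a, ncomp=None):
    a = np.asarray(a)
    el = ET.SubElement(parent, "DataArray")
    el.set("type", "Float64" if a.dtype.kind == "f" else "Int64")
    if name:
        el.set("Name", name)
    if ncomp:
        el.set("NumberOfComponents", str(ncomp))
    el.set("format", "ascii")
    el.text = _fmt_array(a)
    return el


def write_vtu(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    fd = ET.SubElement(grid, "FieldData")
    for name, ids in mesh.node_sets.items():
        _data_array(fd, f"ns:{name}", np.asarray(ids, dtype=np.int64))
    for name, ids in mesh.elem_sets.items():
        _data_array(fd, f"es:{name}", np.asarray(ids, dtype=np.int64))
    for name, ef in mesh.surfaces.items():
        _data_array(fd, f"sf:{name}", np.asarray(ef, dtype=np.int64))
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(mesh.n_nodes),
                          NumberOfCells=str(mesh.n_elems))
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, None, mesh.nodes, ncomp=3)
    cells = ET.SubElement(piece, "Cells")
    conn, offsets, types = [], [], []
    off = 0
    for b in mesh.blocks:
        for row in b.conn:
            conn.extend(int(v) for v in row)
            off += len(row)
            offsets.append(off)
            types.append(VTK_TYPE[b.kind])
    _data_array(cells, "connectivity", np.array(conn, dtype=np.int64))
    _data_array(cells, "offsets", np.array(offsets, dtype=np.int64))
    _data_array(cells, "types", np.array(types, dtype=np.int64))
    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            nc = arr.shape[1] if arr.ndim == 2 else None
            _data_array(pd_el, name, arr, ncomp=nc)
    if cell_data:
        cd_el = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            nc = arr.shape[1] if arr.ndim == 2 else None
            _data_array(cd_el, name, arr, ncomp=nc)
    ET.indent(root)
    Path(path).write_bytes(ET.tostring(root, xml_declaration=True, encoding="utf-8"))


def _parse_array(el) -> np.ndarray:
    text = el.text or ""
    dtype = np.float64 if el.get("type", "").startswith("Float") else np.int64
    parts = text.split()
    if not parts:
        return np.array([], dtype=dtype)
    return np.array(parts, dtype=np.float64).astype(dtype)


def read_vtu(path) -> tuple[Mesh, dict, dict]:
    """Read a VTU written by :func:`write_vtu`; returns (mesh, point_data,
    cell_data)."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML at {exc.position}") from exc
    grid = root.find("UnstructuredGrid")
    if grid is None:
        raise FormatError(f"{path}: not an UnstructuredGrid VTU file")
    piece = grid.find("Piece")
    pts_el = piece.find("Points/DataArray")
    nodes = _parse_array(pts_el).astype(np.float64).reshape(-1, 3)
    arrays = {el.get("Name"): el for el in piece.find("Cells")}
    conn = _parse_array(arrays["connectivity"])
    offsets = _parse_array(arrays["offsets"])
    types = _parse_array(arrays["types"])
    mesh = Mesh(nodes)
    start = 0
    cur_kind, cur_rows = None, []
    for off, t in zip(offsets, types):
        kind = KIND_OF_VTK.get(int(t))
        if kind is None:
            raise FormatError(f"{path}: unsupported VTK cell type {t}")
        row = conn[start:off]
        start = off
        if kind != cur_kind and cur_rows:
            mesh.add_block(cur_kind, np.array(cur_rows, dtype=np.int64))
            cur_rows = []
        cur_kind = kind
        cur_rows.append(row)
    if cur_rows:
        mesh.add_block(cur_kind, np.array(cur_rows, dtype=np.int64))
    fd = grid.find("FieldData")
    if fd is not None:
        for el in fd:
            name = el.get("Name", "")
            data = _parse_array(el).astype(np.int64)
            if name.startswith("ns:"):
                mesh.node_sets[name[3:]] = data
            elif name.startswith("es:"):
                mesh.elem_sets[name[3:]] = data
            elif name.startswith("sf:"):
                mesh.surfaces[name[3:]] = data.reshape(-1, 2)
    point_data, cell_data = {}, {}
    for tag, out, n in (("PointData", point_data, mesh.n_nodes),
                        ("CellData", cell_data, mesh.n_elems)):
        sec = piece.find(tag)
        if sec is not None:
            for el in sec:
                arr = _parse_array(el)
                if len(arr) != n:
                    arr = arr.reshape(n, -1)
                out[el.get("Name")] = arr
    return mesh, point_data, cell_data


# ----------------------------------------------------------------------
# legacy VTK (write-only mesh export)


def write_vtk_legacy(path, mesh: Mesh, cell_data: dict | None = None) -> None:
    lines = ["# vtk DataFile Version 3.0", "cervifem mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    for p in mesh.nodes:
        lines.append(f"{p[0]!r} {p[1]!r} {p[2]!r}")
    total = sum(b.n_elems * (b.conn.shape[1] + 1) for b in mesh.blocks)
    lines.append(f"CELLS {mesh.n_elems} {total}")
    types = []
    for b in mesh.blocks:
        for row in b.conn:
            lines.append(str(len(row)) + " " + " ".join(str(int(v)) for v in row))
            types.append(VTK_TYPE[b.kind])
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines.extend(str(t) for t in types)
    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elems}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float).ravel()
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(repr(float(v)) for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Abaqus INP subset


def write_inp(path, mesh: Mesh, heading: str = "cervifem export") -> None:
    """*NODE / *ELEMENT / *NSET / *ELSET / *SURFACE keyword export (1-based)."""
    out = ["*HEADING", heading, "*NODE"]
    for i, p in enumerate(mesh.nodes, start=1):
        out.append(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}")
    eid = 1
    for bi, b in enumerate(mesh.blocks):
        out.append(f"*ELEMENT, TYPE={INP_TYPE[b.kind]}, ELSET=BLOCK{bi}")
        for row in b.conn:
            out.append(f"{eid}, " + ", ".join(str(int(v) + 1) for v in row))
            eid += 1
    for name, ids in mesh.node_sets.items():
        out.append(f"*NSET, NSET={_inp_name(name)}")
        out.extend(_chunk16(np.asarray(ids) + 1))
    for name, ids in mesh.elem_sets.items():
        out.append(f"*ELSET, ELSET={_inp_name(name)}")
        out.extend(_chunk16(np.asarray(ids) + 1))
    for name, ef in mesh.surfaces.items():
        out.append(f"*SURFACE, NAME={_inp_name(name)}, TYPE=ELEMENT")
        for e, f in np.asarray(ef):
            out.append(f"{int(e) + 1}, {INP_TET_FACE.get(int(f), 'S1')}")
    Path(path).write_text("\n".join(out) + "\n")


def _inp_name(name: str) -> str:
    return name.replace("-", "_").replace(":", "_").upper()


def _chunk16(ids) -> list[str]:
    ids = [str(int(v)) for v in ids]
    return [", ".join(ids[i:i + 16]) for i in range(0, len(ids), 16)]


# ----------------------------------------------------------------------
# model-level dispatch


def write_model(path, model: Model) -> None:
    """Write a model mesh (+ materials as cell data) by file extension."""
    path = Path(path)
    cell_data = {}
    if model.E is not None:
        cell_data["E"] = model.E
        cell_data["nu"] = model.nu
    if model.area is not None:
        cell_data["truss_area"] = model.area
    if path.suffix == ".vtu":
        write_vtu(path, model.mesh, cell_data=cell_data or None)
    elif path.suffix == ".vtk":
        write_vtk_legacy(path, model.mesh, cell_data=cell_data or None)
    elif path.suffix == ".inp":
        write_inp(path, model.mesh)
    else:
        raise FormatError(f"unknown model format {path.suffix!r} "
                          "(supported: .vtu, .vtk, .inp)")


def read_model(path) -> Model:
    """Read a .vtu model file back into a Model (mesh, sets, materials)."""
    path = Path(path)
    if path.suffix != ".vtu":
        raise FormatError(f"unknown model format {path.suffix!r} (read supports .vtu)")
    mesh, _pd, cd = read_vtu(path)
    model = Model(mesh=mesh)
    if "E" in cd:
        model.E = np.asarray(cd["E"], dtype=float)
        model.nu = np.asarray(cd["nu"], dtype=float)
    if "truss_area" in cd:
        model.area = np.asarray(cd["truss_area"], dtype=float)
    return model
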