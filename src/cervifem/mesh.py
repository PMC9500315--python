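"""Mesh container and structured meshing utilities.

All coordinates are millimetres.  Supported element kinds:

========  =====  ==========================================
kind      nodes  use
========  =====  ==========================================
tet4      4      linear tetrahedron (oracle fixtures)
tet10     10     quadratic tetrahedron (default solid)
wedge6    6      linear prism (optional cortical shell)
wedge15   15     quadratic prism (default cortical shell)
truss2    2      tension-only ligament truss
========  =====  ==========================================

Quadratic edge orderings follow the VTK convention:
tet10 edges (0,1),(1,2),(2,0),(0,3),(1,3),(2,3); wedge15 edges
(0,1),(1,2),(2,0),(3,4),(4,5),(5,3),(0,3),(1,4),(2,5).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

NODES_PER_ELEM = {"tet4": 4, "tet10": 10, "wedge6": 6, "wedge15": 15, "truss2": 2, "hex8": 8}

TET10_EDGES = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
WEDGE15_EDGES = [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3), (1, 4), (2, 5)]

# Local faces with outward orientation for a positively oriented element.
TET_FACES = [(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)]
WEDGE_FACES_TRI = [(0, 2, 1), (3, 4, 5)]
WEDGE_FACES_QUAD = [(0, 1, 4, 3), (1, 2, 5, 4), (2, 0, 3, 5)]


class MeshError(ValueError):
    """Raised for malformed or degenerate mesh input."""


@dataclass
class ElementBlock:
    kind: str
    conn: np.ndarray  # (ne, nodes_per_elem) int64

    def __post_init__(self) -> None:
        self.conn = np.ascontiguousarray(self.conn, dtype=np.int64)
        if self.kind not in NODES_PER_ELEM:
            raise MeshError(f"unknown element kind {self.kind!r}")
        if self.conn.ndim != 2 or self.conn.shape[1] != NODES_PER_ELEM[self.kind]:
            raise MeshError(f"bad connectivity shape {self.conn.shape} for {self.kind}")

    @property
    def n_elems(self) -> int:
        return self.conn.shape[0]


@dataclass
class Mesh:
    """Unstructured mesh with named node/element sets and surface patches.

    Element ids are global, counted across ``blocks`` in order.  Surface
    patches are arrays of ``(element_id, local_face_id)`` pairs.
    """

    nodes: np.ndarray
    blocks: list[ElementBlock] = field(default_factory=list)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    elem_sets: dict[str, np.ndarray] = field(default_factory=dict)
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be (n, 3)")

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return sum(b.n_elems for b in self.blocks)

    def element(self, eid: int) -> tuple[str, np.ndarray]:
        """Return (kind, connectivity) of global element ``eid``."""
        for b in self.blocks:
            if eid < b.n_elems:
                return b.kind, b.conn[eid]
            eid -= b.n_elems
        raise IndexError("element id out of range")

    def elem_kinds(self) -> np.ndarray:
        """Array of kind strings, one per global element."""
        out = np.empty(self.n_elems, dtype=object)
        i = 0
        for b in self.blocks:
            out[i : i + b.n_elems] = b.kind
            i += b.n_elems
        return out

    def iter_elements(self):
        """Yield (eid, kind, conn) over all elements."""
        eid = 0
        for b in self.blocks:
            for row in b.conn:
                yield eid, b.kind, row
                eid += 1

    def face_nodes(self, eid: int, face: int) -> np.ndarray:
        """Corner nodes of a local face (quadratic midside nodes ignored)."""
        kind, conn = self.element(eid)
        if kind in ("tet4", "tet10"):
            idx = TET_FACES[face]
        elif kind in ("wedge6", "wedge15"):
            faces = WEDGE_FACES_TRI + WEDGE_FACES_QUAD
            idx = faces[face]
        else:
            raise MeshError(f"{kind} has no faces")
        return conn[list(idx)]

    # ------------------------------------------------------------------
    def add_block(self, kind: str, conn: np.ndarray) -> tuple[int, int]:
        """Append a block; return the (start, stop) global element id range."""
        start = self.n_elems
        self.blocks.append(ElementBlock(kind, conn))
        return start, self.n_elems

    def merge(self, other: "Mesh", prefix: str = "") -> tuple[int, int]:
        """Append ``other`` (nodes, blocks, sets); return its node id offset
        and element id offset in the combined mesh.  Set names from ``other``
        get ``prefix`` prepended."""
        noff = self.n_nodes
        eoff = self.n_elems
        self.nodes = np.vstack([self.nodes, other.nodes])
        for b in other.blocks:
            self.blocks.append(ElementBlock(b.kind, b.conn + noff))
        for name, ids in other.node_sets.items():
            self.node_sets[prefix + name] = np.asarray(ids, dtype=np.int64) + noff
        for name, ids in other.elem_sets.items():
            self.elem_sets[prefix + name] = np.asarray(ids, dtype=np.int64) + eoff
        for name, ef in other.surfaces.items():
            ef = np.asarray(ef, dtype=np.int64).copy()
            ef[:, 0] += eoff
            self.surfaces[prefix + name] = ef
        return noff, eoff

    # ------------------------------------------------------------------
    def element_volumes(self) -> np.ndarray:
        """Volume (mm^3) per solid element, length (mm) for trusses."""
        vols = np.zeros(self.n_elems)
        for eid, kind, conn in self.iter_elements():
            x = self.nodes[conn]
            if kind in ("tet4", "tet10"):
                vols[eid] = tet_volume(x[:4])
            elif kind in ("wedge6", "wedge15"):
                vols[eid] = wedge_volume(x[:6])
            elif kind == "truss2":
                vols[eid] = np.linalg.norm(x[1] - x[0])
            elif kind == "hex8":
                vols[eid] = hex_volume(x)
        return vols

    def element_centroids(self) -> np.ndarray:
        cents = np.zeros((self.n_elems, 3))
        for eid, kind, conn in self.iter_elements():
            ncorner = {"tet4": 4, "tet10": 4, "wedge6": 6, "wedge15": 6, "truss2": 2, "hex8": 8}[kind]
            cents[eid] = self.nodes[conn[:ncorner]].mean(axis=0)
        return cents

    def content_hash(self) -> str:
        """SHA-256 of the full mesh content (determinism contract)."""
        h = hashlib.sha256()
        h.update(self.nodes.tobytes())
        for b in self.blocks:
            h.update(b.kind.encode())
            h.update(b.conn.tobytes())
        for coll in (self.node_sets, self.elem_sets, self.surfaces):
            for name in sorted(coll):
                h.update(name.encode())
                h.update(np.ascontiguousarray(coll[name], dtype=np.int64).tobytes())
        return h.hexdigest()


# ----------------------------------------------------------------------
# geometric primitives


def tet_volume(x: np.ndarray) -> float:
    return float(np.linalg.det(np.array([x[1] - x[0], x[2] - x[0], x[3] - x[0]])) / 6.0)


def wedge_volume(x: np.ndarray) -> float:
    """Volume of a 6-node prism by splitting into 3 tets."""
    t = [(0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 5)]
    return sum(abs(tet_volume(x[list(ti)])) for ti in t)


def hex_volume(x: np.ndarray) -> float:
    tets = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
    return sum(abs(tet_volume(x[list(t)])) for t in tets)


# 6-tet decomposition around the 0-6 main diagonal; face-conforming on a
# structured grid when every hex uses the same local vertex ordering.
HEX_TO_TETS = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]


def structured_hexes(nx: int, ny: int, nz: int) -> np.ndarray:
    """Hex connectivity of an (nx, ny, nz)-cell structured grid whose nodes
    are ordered with k fastest, then j, then i... here: index = (i*(ny+1)+j)*(nz+1)+k."""

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    return np.array(hexes, dtype=np.int64)


def hexes_to_tets(hexes: np.ndarray) -> np.ndarray:
    """Split hexes into 6 tets each (consistent, face-conforming pattern)."""
    out = np.empty((hexes.shape[0] * 6, 4), dtype=np.int64)
    for t, pat in enumerate(HEX_TO_TETS):
        out[t::6] = hexes[:, list(pat)]
    return out


def fix_tet_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap nodes so every tet has positive volume."""
    tets = tets.copy()
    for row in tets:
        if tet_volume(nodes[row]) < 0:
            row[1], row[2] = row[2], row[1]
    return tets


def square_to_ellipse(u: np.ndarray, v: np.ndarray, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical grid mapping of the square [-1,1]^2 onto an ellipse with
    semi-axes a (x) and b (y).  Bijective; boundary maps exactly to the
    ellipse."""
    x = a * u * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * v * v))
    y = b * v * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * u * u))
    return x, y


def elliptic_cylinder(a: float, b: float, h: float, n_cross: int, n_z: int,
                      z0: float = 0.0) -> Mesh:
    """Structured tet4 mesh of an elliptic cylinder (axis z, z in [z0, z0+h]).

    ``n_cross`` cells across each in-plane direction, ``n_z`` cells axially.
    Node sets: ``bottom``, ``top``, ``lateral`` (side wall).
    """
    if min(a, b, h) <= 0:
        raise MeshError("elliptic cylinder dimensions must be positive")
    u = np.linspace(-1, 1, n_cross + 1)
    zs = np.linspace(z0, z0 + h, n_z + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    xx, yy = square_to_ellipse(uu, vv, a, b)
    nodes = np.empty(((n_cross + 1) ** 2 * (n_z + 1), 3))
    idx = 0
    for i in range(n_cross + 1):
        for j in range(n_cross + 1):
            for k in range(n_z + 1):
                nodes[idx] = (xx[i, j], yy[i, j], zs[k])
                idx += 1
    hexes = structured_hexes(n_cross, n_cross, n_z)
    tets = fix_tet_orientation(nodes, hexes_to_tets(hexes))
    m = Mesh(nodes)
    m.add_block("tet4", tets)

    def nid(i, j, k):
        return (i * (n_cross + 1) + j) * (n_z + 1) + k

    bottom = [nid(i, j, 0) for i in range(n_cross + 1) for j in range(n_cross + 1)]
    top = [nid(i, j, n_z) for i in range(n_cross + 1) for j in range(n_cross + 1)]
    lateral = [
        nid(i, j, k)
        for i in range(n_cross + 1)
        for j in range(n_cross + 1)
        if i in (0, n_cross) or j in (0, n_cross)
        for k in range(n_z + 1)
    ]
    m.node_sets["bottom"] = np.array(sorted(bottom), dtype=np.int64)
    m.node_sets["top"] = np.array(sorted(top), dtype=np.int64)
    m.node_sets["lateral"] = np.array(sorted(set(lateral)), dtype=np.int64)
    return m


def box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int,
             origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Mesh:
    """Structured tet4 mesh of a box. Node sets: bottom, top, xmin/xmax/ymin/ymax."""
    if min(lx, ly, lz) <= 0:
        raise MeshError("box dimensions must be positive")
    xs = np.linspace(origin[0], origin[0] + lx, nx + 1)
    ys = np.linspace(origin[1], origin[1] + ly, ny + 1)
    zs = np.linspace(origin[2], origin[2] + lz, nz + 1)
    nodes = np.empty(((nx + 1) * (ny + 1) * (nz + 1), 3))
    idx = 0
    for i in range(nx + 1):
        for j in range(ny + 1):
            for k in range(nz + 1):
                nodes[idx] = (xs[i], ys[j], zs[k])
                idx += 1
    hexes = structured_hexes(nx, ny, nz)
    tets = fix_tet_orientation(nodes, hexes_to_tets(hexes))
    m = Mesh(nodes)
    m.add_block("tet4", tets)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    m.node_sets["bottom"] = np.array(
        sorted(nid(i, j, 0) for i in range(nx + 1) for j in range(ny + 1)), dtype=np.int64)
    m.node_sets["top"] = np.array(
        sorted(nid(i, j, nz) for i in range(nx + 1) for j in range(ny + 1)), dtype=np.int64)
    m.node_sets["xmin"] = np.array(
        sorted(nid(0, j, k) for j in range(ny + 1) for k in range(nz + 1)), dtype=np.int64)
    m.node_sets["xmax"] = np.array(
        sorted(nid(nx, j, k) for j in range(ny + 1) for k in range(nz + 1)), dtype=np.int64)
    m.node_sets["ymin"] = np.array(
        sorted(nid(i, 0, k) for i in range(nx + 1) for k in range(nz + 1)), dtype=np.int64)
    m.node_sets["ymax"] = np.array(
        sorted(nid(i, ny, k) for i in range(nx + 1) for k in range(nz + 1)), dtype=np.int64)
    return m


# ----------------------------------------------------------------------
# quadratic conversion, boundary extraction, shells, node merging


def tet4_to_tet10(mesh: Mesh) -> Mesh:
    """Convert every tet4 block to tet10 by inserting shared edge midpoints.

    Node sets are widened: a midpoint joins every node set that contains both
    of its edge endpoints (so surface sets stay surface sets).
    """
    new_nodes = [mesh.nodes]
    edge_mid: dict[tuple[int, int], int] = {}
    nn = mesh.n_nodes

    def midpoint(i: int, j: int) -> int:
        nonlocal nn
        key = (i, j) if i < j else (j, i)
        if key not in edge_mid:
            edge_mid[key] = nn
            new_nodes.append(0.5 * (mesh.nodes[key[0]] + mesh.nodes[key[1]]))
            nn += 1
        return edge_mid[key]

    out = Mesh(mesh.nodes.copy())
    out.node_sets = {k: v.copy() for k, v in mesh.node_sets.items()}
    out.elem_sets = {k: v.copy() for k, v in mesh.elem_sets.items()}
    out.surfaces = {k: v.copy() for k, v in mesh.surfaces.items()}
    for b in mesh.blocks:
        if b.kind != "tet4":
            out.blocks.append(ElementBlock(b.kind, b.conn.copy()))
            continue
        conn10 = np.empty((b.n_elems, 10), dtype=np.int64)
        conn10[:, :4] = b.conn
        for e, row in enumerate(b.conn):
            for m_i, (i, j) in enumerate(TET10_EDGES):
                conn10[e, 4 + m_i] = midpoint(row[i], row[j])
        out.blocks.append(ElementBlock("tet10", conn10))
    flat = np.vstack([mesh.nodes] + [np.atleast_2d(p) for p in new_nodes[1:]]) \
        if len(new_nodes) > 1 else mesh.nodes.copy()
    out.nodes = flat
    # widen node sets with midpoints interior to them
    for name, ids in mesh.node_sets.items():
        s = set(int(i) for i in ids)
        extra = [mid for (i, j), mid in edge_mid.items() if i in s and j in s]
        if extra:
            out.node_sets[name] = np.array(sorted(s | set(extra)), dtype=np.int64)
    return out


def boundary_faces(mesh: Mesh, elem_ids: np.ndarray | None = None) -> np.ndarray:
    """Boundary (unshared) triangular corner faces of the tet elements.

    Returns an array of (eid, local_face) pairs, suitable as a surface patch.
    """
    count: dict[tuple[int, ...], list] = {}
    sel = None if elem_ids is None else set(int(e) for e in elem_ids)
    for eid, kind, conn in mesh.iter_elements():
        if kind not in ("tet4", "tet10"):
            continue
        if sel is not None and eid not in sel:
            continue
        for f, idx in enumerate(TET_FACES):
            tri = tuple(sorted(int(conn[i]) for i in idx))
            count.setdefault(tri, []).append((eid, f))
    out = [pairs[0] for pairs in count.values() if len(pairs) == 1]
    return np.array(sorted(out), dtype=np.int64).reshape(-1, 2)


def surface_triangles(mesh: Mesh, patch: np.ndarray) -> np.ndarray:
    """(nf, 3) corner-node triangles of a surface patch, outward-oriented."""
    return np.array([mesh.face_nodes(int(e), int(f)) for e, f in patch], dtype=np.int64)


def node_normals(mesh: Mesh, tris: np.ndarray) -> dict[int, np.ndarray]:
    """Area-weighted unit outward normals at the nodes of a triangle fan."""
    acc: dict[int, np.ndarray] = {}
    for tri in tris:
        x = mesh.nodes[tri]
        n = np.cross(x[1] - x[0], x[2] - x[0])
        for nid in tri:
            acc[int(nid)] = acc.get(int(nid), np.zeros(3)) + 0.5 * n
    return {k: v / np.linalg.norm(v) for k, v in acc.items()}


def merge_pairs_map(n_nodes: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Union-find representative map for node-equivalence (DOF merging)."""
    parent = np.arange(n_nodes, dtype=np.int64)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    for i in range(n_nodes):
        parent[i] = find(i)
    return parent


def nearest_node_pairs(nodes_a: np.ndarray, ids_a: np.ndarray,
                       nodes_all: np.ndarray, ids_b: np.ndarray,
                       max_dist: float) -> list[tuple[int, int]]:
    """Pair each node in ids_a with its nearest node in ids_b within max_dist."""
    from scipy.spatial import cKDTree

    if len(ids_a) == 0 or len(ids_b) == 0:
        return []
    tree = cKDTree(nodes_all[ids_b])
    d, j = tree.query(nodes_a[ids_a])
    return [(int(ia), int(ids_b[jj])) for ia, dd, jj in zip(ids_a, d, j) if dd <= max_dist]


# ----------------------------------------------------------------------
# mesh quality (inspection-style report)


def mesh_quality(mesh: Mesh, jac_gate: float = 0.2, skew_gate: float = 0.995,
                 collapse_gate: float = 0.05) -> dict[str, float]:
    """Tet quality inspection report.

    Metrics per tet: shape quality 6*sqrt(2)*V / L_max^3 (1.0 for the
    regular tet, ~0.5 for the right tets of a structured hex split), volume
    skew 1 - V / V_equilateral(circumradius), and collapse = min altitude /
    max edge.  Returns the extreme values and the percentage of elements
    beyond each gate; gates are calibrated to the structured-split element
    shapes the generator produces.
    """
    jac, skew, coll = [], [], []
    for eid, kind, conn in mesh.iter_elements():
        if kind not in ("tet4", "tet10"):
            continue
        x = mesh.nodes[conn[:4]]
        v = abs(tet_volume(x))
        edges = [np.linalg.norm(x[i] - x[j]) for i in range(4) for j in range(i + 1, 4)]
        lmax = max(edges)
        areas = []
        for f in TET_FACES:
            p = x[list(f)]
            areas.append(0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))
        hmin = min(3.0 * v / a for a in areas)
        coll.append(hmin / lmax)
        # circumradius
        A = 2.0 * (x[1:] - x[0])
        bvec = np.sum(x[1:] ** 2 - x[0] ** 2, axis=1)
        try:
            c = np.linalg.solve(A, bvec)
            r = np.linalg.norm(c - x[0])
            v_reg = (8.0 / (9.0 * np.sqrt(3.0))) * r**3
            skew.append(1.0 - v / v_reg)
        except np.linalg.LinAlgError:
            skew.append(1.0)
        jac.append(6.0 * v / lmax**3 * np.sqrt(2.0))  # 1.0 for the regular tet
    jac, skew, coll = map(np.asarray, (jac, skew, coll))
    n = max(len(jac), 1)
    return {
        "n_tets": int(len(jac)),
        "jacobian_min": float(jac.min()) if len(jac) else float("nan"),
        "skew_max": float(skew.max()) if len(skew) else float("nan"),
        "collapse_min": float(coll.min()) if len(coll) else float("nan"),
        "pct_jacobian_poor": float(100.0 * np.mean(jac < jac_gate)) if len(jac) else 0.0,
        "pct_skew_poor": float(100.0 * np.mean(skew > skew_gate)) if len(skew) else 0.0,
        "pct_collapse_poor": float(100.0 * np.mean(coll < collapse_gate)) if len(coll) else 0.0,
        "n_checked": n,
    }
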