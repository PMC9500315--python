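"""Parametric synthetic C2-T2 spine phantom with discs, ligaments and
anterior instrumentation.

The phantom is a stylized stand-in for a patient-specific reconstruction:
each vertebra is an elliptic-cylinder trabecular body (partitioned into a
central and an exterior region) plus a posterior block carrying the
spinous/articular landmarks, wrapped laterally by a one-element cortical
wedge shell of prescribed thickness (0.28 mm cervical / 0.24 mm thoracic).
Discs are concentric nucleus-pulposus / anulus-fibrosus rings whose NP
endplate-area share and volume share are controlled independently (the NP
boundary bulges towards mid-height).  Six ligament groups are mapped as one
tension-only truss per unit per junction.  The ACDF construct (three PEEK
spacers, a four-level anterior titanium plate, eight screws) replaces the
C2-C5 discs and is bonded to bone by node equivalence.

Global axes: x lateral, y anteroposterior (anterior = -y), z vertical
(superior = +z).  T2 sits at z = 0; levels stack upward to C2.  All
lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import ContactPair, Coupling, Model, Mpc
from .materials import LIGAMENT_CARDS
from .mesh import (Mesh, boundary_faces, box_mesh, elliptic_cylinder,
                   fix_tet_orientation, hexes_to_tets, nearest_node_pairs,
                   square_to_ellipse, structured_hexes, surface_triangles,
                   node_normals, tet4_to_tet10, TET_FACES, TET10_EDGES)

CERVICAL = ("C2", "C3", "C4", "C5", "C6", "C7")
THORACIC = ("T1", "T2")
LEVELS = CERVICAL + THORACIC
JUNCTIONS = tuple(f"{a}-{b}" for a, b in zip(LEVELS[:-1], LEVELS[1:]))
CONTACT_JUNCTIONS = ("C5-C6", "C6-C7", "C7-T1", "T1-T2")

#: default ligament truss units per group per junction (ITL and LF are the
#: paired left/right groups)
LIGAMENT_UNITS = {"ALL": 1, "PLL": 1, "ISL": 1, "SSL": 1, "ITL": 2, "LF": 2}


class SpecificationError(ValueError):
    """Invalid phantom/instrument parameters (dimension, fraction, span)."""


class ResolutionError(ValueError):
    """Mesh size cannot resolve the requested feature."""


class GeometryError(ValueError):
    """Generated geometry is inconsistent (screw through the body wall...)."""


class AssemblyError(RuntimeError):
    """Missing landmark/set during phantom assembly."""


# ----------------------------------------------------------------------
# specs


def _default_dims() -> dict[str, tuple[float, float, float]]:
    # C2 (the axis) is substantially wider than the subaxial bodies: its
    # load-bearing cross-section includes the fused lateral masses.
    dims = {"C2": (22.0, 18.0, 12.0)}
    for lv in CERVICAL[1:]:
        dims[lv] = (16.0, 14.0, 11.0)
    for lv in THORACIC:
        dims[lv] = (16.0, 14.0, 13.0)
    return dims


@dataclass
class PhantomSpec:
    """Geometry parameters of the synthetic spine."""

    levels: tuple[str, ...] = LEVELS
    body_dims: dict[str, tuple[float, float, float]] = field(default_factory=_default_dims)
    disc_height: float = 5.0
    np_area_fraction: float = 0.43
    np_volume_fraction: float = 0.45
    cortical_thickness_cervical: float = 0.28
    cortical_thickness_thoracic: float = 0.24
    mesh_size: float = 3.0
    facet_gap: float = 0.3
    facet_angle: float = 20.0   # degrees; bilateral facet inclination
    quadratic: bool = True
    jitter: float = 0.0
    seed: int = 0
    ssl_merged_junctions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        dims = _default_dims()
        dims.update(self.body_dims)
        self.body_dims = dims
        for lv in self.levels:
            w, d, h = self.body_dims[lv]
            if min(w, d, h) <= 0:
                raise SpecificationError(f"{lv}: body dimensions must be > 0, got {(w, d, h)}")
        if self.disc_height <= 0:
            raise SpecificationError("disc_height must be > 0")
        if not (0.25 <= self.np_area_fraction <= 0.50):
            raise SpecificationError(
                f"np_area_fraction {self.np_area_fraction} outside [0.25, 0.50]")
        if not (0.40 <= self.np_volume_fraction <= 0.50):
            raise SpecificationError(
                f"np_volume_fraction {self.np_volume_fraction} outside [0.40, 0.50]")
        if self.cortical_thickness_cervical <= 0 or self.cortical_thickness_thoracic <= 0:
            raise SpecificationError("cortical thickness must be > 0")
        if not (0.0 <= self.facet_angle < 45.0):
            raise SpecificationError("facet_angle must lie in [0, 45) degrees")
        if self.mesh_size <= 0:
            raise SpecificationError("mesh_size must be > 0")
        tmin = min(self.cortical_thickness_cervical, self.cortical_thickness_thoracic)
        if self.mesh_size > 50.0 * tmin:
            raise ResolutionError(
                f"mesh_size={self.mesh_size} too large to resolve the cortical layer "
                f"(thickness {tmin} mm): reduce mesh_size")
        wmin = min(self.body_dims[lv][0] for lv in self.levels)
        if self.mesh_size > wmin / 3.0:
            raise ResolutionError(
                f"mesh_size={self.mesh_size} too large for the smallest body width "
                f"{wmin} mm: reduce mesh_size")

    # resolution helpers ------------------------------------------------
    def n_cross(self, width: float | None = None) -> int:
        """Cross-section cells.  One shared value (from the widest body) for
        bodies/discs/spacers so stacked grids coincide node-for-node."""
        if width is None:
            width = max(self.body_dims[lv][0] for lv in self.levels)
        return max(4, int(np.ceil(width / self.mesh_size)))

    def n_axial(self, height: float) -> int:
        return max(2, int(np.ceil(height / self.mesh_size)))

    def dims(self, level: str) -> tuple[float, float, float]:
        if level not in self.body_dims:
            raise SpecificationError(f"unknown level {level!r}")
        return self.body_dims[level]

    def cortical_thickness(self, level: str) -> float:
        return (self.cortical_thickness_cervical if level.startswith("C")
                else self.cortical_thickness_thoracic)

    @property
    def junctions(self) -> tuple[str, ...]:
        return tuple(f"{a}-{b}" for a, b in zip(self.levels[:-1], self.levels[1:]))


@dataclass
class InstrumentSpec:
    """ACDF construct: spacers, anterior plate, fixation screws."""

    spacer_heights: tuple[float, ...] = (8.0, 8.0, 7.0)
    screw_diameter: float = 4.0
    screw_length: float = 15.0
    plate_length: float = 55.0
    plate_width: float = 16.0
    plate_thickness: float = 2.25
    plate_span: tuple[str, ...] = ("C2", "C3", "C4", "C5")
    plate_standoff: float = 0.0

    def __post_init__(self) -> None:
        if self.screw_length <= 0 or self.screw_diameter <= 0:
            raise SpecificationError("screw dimensions must be > 0")
        if self.plate_standoff < 0:
            raise SpecificationError("plate_standoff must be >= 0")
        if any(h <= 0 for h in self.spacer_heights):
            raise SpecificationError("spacer heights must be > 0")
        idx = [LEVELS.index(lv) for lv in self.plate_span]
        if idx != list(range(min(idx), min(idx) + len(idx))):
            raise SpecificationError("plate_span must be contiguous vertebra labels")
        if len(self.spacer_heights) != len(self.plate_span) - 1:
            raise SpecificationError(
                f"{len(self.spacer_heights)} spacers for {len(self.plate_span) - 1} "
                "spanned junctions")

    @property
    def spanned_junctions(self) -> tuple[str, ...]:
        return tuple(f"{a}-{b}" for a, b in zip(self.plate_span[:-1], self.plate_span[1:]))

    @property
    def all_resected_span(self) -> tuple[str, ...]:
        return self.spanned_junctions


# ----------------------------------------------------------------------
# vertebra


def _tet10_face_nodes(conn: np.ndarray, face: int) -> np.ndarray:
    """Six nodes (3 corners + 3 midsides) of a tet10 face."""
    ca, cb, cc = TET_FACES[face]
    corners = [conn[ca], conn[cb], conn[cc]]
    mids = []
    for i, j in ((ca, cb), (cb, cc), (cc, ca)):
        for m, (ei, ej) in enumerate(TET10_EDGES):
            if {ei, ej} == {i, j}:
                mids.append(conn[4 + m])
                break
    return np.array(corners + mids, dtype=np.int64)


def _add_cortical_shell(mesh: Mesh, body_elems: np.ndarray, thickness: float,
                        quadratic: bool) -> None:
    """Offset a one-element wedge layer outward from the lateral body surface."""
    patch = boundary_faces(mesh, body_elems)
    # keep circumferential faces only (endplates stay trabecular for disc ties)
    keep = []
    for e, f in patch:
        tri = mesh.face_nodes(int(e), int(f))
        x = mesh.nodes[tri]
        n = np.cross(x[1] - x[0], x[2] - x[0])
        n = n / np.linalg.norm(n)
        if abs(n[2]) < 0.5:
            keep.append((int(e), int(f)))
    if not keep:
        raise AssemblyError("no lateral surface found for cortical shell")
    patch = np.array(keep, dtype=np.int64)
    mesh.surfaces["body_lateral"] = patch
    tris = surface_triangles(mesh, patch)
    normals = node_normals(mesh, tris)

    new_nodes: list[np.ndarray] = []
    outer_of: dict[int, int] = {}
    mid_of: dict[int, int] = {}
    nn = mesh.n_nodes

    def outer(nid: int) -> int:
        nonlocal nn
        if nid not in outer_of:
            outer_of[nid] = nn
            new_nodes.append(mesh.nodes[nid] + thickness * normals[nid])
            nn += 1
        return outer_of[nid]

    def vmid(nid: int) -> int:
        nonlocal nn
        if nid not in mid_of:
            mid_of[nid] = nn
            new_nodes.append(mesh.nodes[nid] + 0.5 * thickness * normals[nid])
            nn += 1
        return mid_of[nid]

    conns = []
    if quadratic:
        # midside normals: average of the edge's corner normals
        for (e, f), tri in zip(patch, tris):
            _kind, conn = mesh.element(int(e))
            fn = _tet10_face_nodes(conn, int(f))
            c0, c1, c2, m01, m12, m20 = (int(i) for i in fn)
            for mid, (i, j) in ((m01, (c0, c1)), (m12, (c1, c2)), (m20, (c2, c0))):
                if mid not in normals:
                    v = normals[i] + normals[j]
                    normals[mid] = v / np.linalg.norm(v)
            row = [c0, c1, c2, outer(c0), outer(c1), outer(c2),
                   m01, m12, m20, outer(m01), outer(m12), outer(m20),
                   vmid(c0), vmid(c1), vmid(c2)]
            conns.append(row)
        kind = "wedge15"
    else:
        for tri in tris:
            c0, c1, c2 = (int(i) for i in tri)
            conns.append([c0, c1, c2, outer(c0), outer(c1), outer(c2)])
        kind = "wedge6"
    mesh.nodes = np.vstack([mesh.nodes] + [p[None, :] for p in new_nodes])
    start, stop = mesh.add_block(kind, np.array(conns, dtype=np.int64))
    mesh.elem_sets["cortical"] = np.arange(start, stop, dtype=np.int64)


def generate_vertebra(spec: PhantomSpec, level: str,
                      extend_sup: float = 0.0, extend_inf: float = 0.0) -> Mesh:
    """One stylized vertebra in local coordinates (body z in [0, h]).

    Element sets: ``central_body``, ``exterior_body``, ``posterior``,
    ``cortical``.  Node sets: ``endplate_sup``/``endplate_inf``, ``lateral``,
    ``spinous``, ``blk_anterior``, ``facet_sup_nodes``/``facet_inf_nodes``,
    and for C2 the paired ``odontoid_facet_left``/``odontoid_facet_right``.
    Surface patches ``facet_sup``/``facet_inf`` sit on the posterior block.
    """
    if level not in spec.levels:
        raise SpecificationError(f"level {level!r} not in spec.levels")
    w, d, h = spec.dims(level)
    a, b = w / 2.0, d / 2.0
    n_c, n_z = spec.n_cross(), spec.n_axial(h)
    mesh = elliptic_cylinder(a, b, h, n_c, n_z)
    n_body = mesh.n_elems
    cents = mesh.element_centroids()
    rho = np.sqrt((cents[:, 0] / a) ** 2 + (cents[:, 1] / b) ** 2)
    body_ids = np.arange(n_body, dtype=np.int64)
    mesh.elem_sets["central_body"] = body_ids[rho < 0.6]
    mesh.elem_sets["exterior_body"] = body_ids[rho >= 0.6]
    mesh.node_sets["endplate_inf"] = mesh.node_sets.pop("bottom")
    mesh.node_sets["endplate_sup"] = mesh.node_sets.pop("top")

    # posterior block carrying spinous/articular landmarks
    wb, db = 0.5 * w, 0.75 * d
    y0 = 0.80 * b   # anterior block face strictly inside the body ellipse
    z_lo, z_hi = -extend_inf, h + extend_sup
    blk = box_mesh(wb, db, z_hi - z_lo,
                   max(2, int(np.ceil(wb / spec.mesh_size))),
                   max(2, int(np.ceil(db / spec.mesh_size))),
                   max(2, int(np.ceil((z_hi - z_lo) / spec.mesh_size))),
                   origin=(-wb / 2.0, y0, z_lo))
    if spec.facet_angle > 0:
        # bilateral facet inclination: shear the block towards a roof shape
        # (apex on the midline) so the articular faces interlock laterally,
        # resisting axial rotation and lateral shear like real facets
        beta = np.radians(spec.facet_angle)
        z_c = 0.5 * (z_lo + z_hi)
        half = max(0.5 * (z_hi - z_lo), 1e-9)
        wgt = np.abs(blk.nodes[:, 2] - z_c) / half
        blk.nodes[:, 2] -= wgt * np.abs(blk.nodes[:, 0]) * np.tan(beta)
    noff, eoff = mesh.merge(blk, prefix="blk_")
    mesh.elem_sets["posterior"] = np.arange(eoff, mesh.n_elems, dtype=np.int64)
    mesh.node_sets["facet_inf_nodes"] = mesh.node_sets.pop("blk_bottom")
    mesh.node_sets["facet_sup_nodes"] = mesh.node_sets.pop("blk_top")
    mesh.node_sets["spinous"] = mesh.node_sets.pop("blk_ymax")
    mesh.node_sets["blk_anterior"] = mesh.node_sets.pop("blk_ymin")
    for junk in ("blk_xmin", "blk_xmax"):
        mesh.node_sets.pop(junk, None)

    if spec.jitter > 0:
        rng = np.random.default_rng((spec.seed * 97 + spec.levels.index(level)) % 2**31)
        onsurf = set()
        for ids in mesh.node_sets.values():
            onsurf.update(int(i) for i in ids)
        interior = np.array([i for i in range(mesh.n_nodes) if i not in onsurf],
                            dtype=np.int64)
        if len(interior):
            mesh.nodes[interior] += (spec.jitter * spec.mesh_size *
                                     rng.uniform(-0.5, 0.5, (len(interior), 3)))

    if spec.quadratic:
        mesh = tet4_to_tet10(mesh)

    # articular facet surfaces on the posterior block (faces all of whose
    # corners lie on the block's sheared top/bottom grid surface)
    post = mesh.elem_sets["posterior"]
    bpatch = boundary_faces(mesh, post)
    sup_nodes = set(int(n) for n in mesh.node_sets["facet_sup_nodes"])
    inf_nodes = set(int(n) for n in mesh.node_sets["facet_inf_nodes"])
    sup_faces, inf_faces = [], []
    for e, f in bpatch:
        tri = mesh.face_nodes(int(e), int(f))
        if all(int(n) in sup_nodes for n in tri):
            sup_faces.append((int(e), int(f)))
        elif all(int(n) in inf_nodes for n in tri):
            inf_faces.append((int(e), int(f)))
    mesh.surfaces["facet_sup"] = np.array(sorted(sup_faces), dtype=np.int64).reshape(-1, 2)
    mesh.surfaces["facet_inf"] = np.array(sorted(inf_faces), dtype=np.int64).reshape(-1, 2)

    _add_cortical_shell(mesh, body_ids, spec.cortical_thickness(level), spec.quadratic)

    if level == "C2":
        sup = mesh.node_sets["endplate_sup"]
        xy = mesh.nodes[sup]
        anterolateral = (xy[:, 1] < 0.2 * b) & (np.abs(xy[:, 0]) > 0.3 * a)
        left = sup[anterolateral & (mesh.nodes[sup][:, 0] < 0)]
        right = sup[anterolateral & (mesh.nodes[sup][:, 0] > 0)]
        if len(left) == 0 or len(right) == 0:
            raise AssemblyError("C2 odontoid facet patches are empty; refine mesh_size")
        mesh.node_sets["odontoid_facet_left"] = left
        mesh.node_sets["odontoid_facet_right"] = right
    return mesh


# ----------------------------------------------------------------------
# disc / spacer


def _annular_solid(a: float, b: float, h: float, n_c: int, n_z: int,
                   layer_targets=None,
                   top_dims: tuple[float, float] | None = None
                   ) -> tuple[Mesh, np.ndarray]:
    """Elliptic-cylinder mesh that tracks which cells belong to the core.

    ``layer_targets`` gives the target core area share per z-layer; the
    core is chosen greedily from the innermost cells.  ``top_dims`` (a, b)
    tapers the footprint linearly from (a, b) at the bottom to the top
    values, so both faces can coincide node-for-node with differently sized
    endplate grids.  Returns the mesh and a bool array over tets flagging
    core membership.
    """
    a1, b1 = top_dims if top_dims is not None else (a, b)
    u = np.linspace(-1, 1, n_c + 1)
    zs = np.linspace(0.0, h, n_z + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    nodes = np.empty(((n_c + 1) ** 2 * (n_z + 1), 3))
    xk, yk = [], []
    for k in range(n_z + 1):
        t = zs[k] / h
        xx, yy = square_to_ellipse(uu, vv, (1 - t) * a + t * a1, (1 - t) * b + t * b1)
        xk.append(xx)
        yk.append(yy)
    idx = 0
    for i in range(n_c + 1):
        for j in range(n_c + 1):
            for k in range(n_z + 1):
                nodes[idx] = (xk[k][i, j], yk[k][i, j], zs[k])
                idx += 1
    hexes = structured_hexes(n_c, n_c, n_z)
    tets = fix_tet_orientation(nodes, hexes_to_tets(hexes))
    mesh = Mesh(nodes)
    mesh.add_block("tet4", tets)

    # per-cell footprint area (at each layer's mid-height) and centre radius
    cell_rho = np.zeros((n_c, n_c))
    for i in range(n_c):
        for j in range(n_c):
            uc, vc = 0.5 * (u[i] + u[i + 1]), 0.5 * (u[j] + u[j + 1])
            cell_rho[i, j] = np.sqrt(uc**2 + vc**2 - uc**2 * vc**2)
    order = np.dstack(np.unravel_index(np.argsort(cell_rho, axis=None),
                                       cell_rho.shape))[0]

    core = np.zeros(len(tets), dtype=bool)
    if layer_targets is not None:
        # tets of hex (i, j, k): hex index (i*n_c + j)*n_z + k, 6 tets each
        for k in range(n_z):
            t = (zs[k] + zs[k + 1]) / (2.0 * h)
            am, bm = (1 - t) * a + t * a1, (1 - t) * b + t * b1
            xx, yy = square_to_ellipse(uu, vv, am, bm)
            cell_area = np.zeros((n_c, n_c))
            for i in range(n_c):
                for j in range(n_c):
                    quad = np.array([
                        [xx[i, j], yy[i, j]], [xx[i + 1, j], yy[i + 1, j]],
                        [xx[i + 1, j + 1], yy[i + 1, j + 1]], [xx[i, j + 1], yy[i, j + 1]]])
                    s = 0.0
                    for q4 in range(4):
                        p, q = quad[q4], quad[(q4 + 1) % 4]
                        s += p[0] * q[1] - q[0] * p[1]
                    cell_area[i, j] = abs(s) / 2.0
            total = cell_area.sum()
            target = layer_targets[k] * total
            acc = 0.0
            chosen = []
            for (i, j) in order:
                if abs(acc + cell_area[i, j] - target) >= abs(acc - target):
                    break
                acc += cell_area[i, j]
                chosen.append((i, j))
            for (i, j) in chosen:
                hx = (i * n_c + j) * n_z + k
                core[6 * hx:6 * hx + 6] = True

    def nid(i, j, k):
        return (i * (n_c + 1) + j) * (n_z + 1) + k

    mesh.node_sets["inf"] = np.array(
        sorted(nid(i, j, 0) for i in range(n_c + 1) for j in range(n_c + 1)), dtype=np.int64)
    mesh.node_sets["sup"] = np.array(
        sorted(nid(i, j, n_z) for i in range(n_c + 1) for j in range(n_c + 1)), dtype=np.int64)
    return mesh, core


def generate_disc(spec: PhantomSpec, junction: str,
                  height: float | None = None,
                  dims: tuple[float, float] | None = None) -> Mesh:
    """Concentric NP-core / AF-ring disc for a junction.

    The NP endplate-area share follows ``np_area_fraction`` and the NP
    boundary widens parabolically towards mid-height so the volume share
    meets ``np_volume_fraction`` independently.  Element sets ``NP``/``AF``;
    node sets ``sup``/``inf`` flag the tying surfaces.
    """
    if junction not in spec.junctions:
        raise SpecificationError(f"unknown junction {junction!r}")
    up, lo = junction.split("-")
    if dims is None:
        wu, du, _ = spec.dims(up)
        wl, dl, _ = spec.dims(lo)
        a, b = wl / 2.0, dl / 2.0            # bottom face: lower endplate
        top = (wu / 2.0, du / 2.0)           # top face: upper endplate
    else:
        a, b = dims[0] / 2.0, dims[1] / 2.0
        top = None
    h = spec.disc_height if height is None else height
    if h <= 0:
        raise SpecificationError("disc height must be > 0")
    fa, fv = spec.np_area_fraction, spec.np_volume_fraction
    n_c = spec.n_cross()
    # >= 3 layers so the endplate share (fa) and the bulged interior layers
    # (carrying the volume share fv) are independent
    n_z = max(3, int(np.ceil(h / spec.mesh_size)))
    targets = np.full(n_z, fa)
    if n_z > 2:
        t_int = (fv * n_z - 2.0 * fa) / (n_z - 2)
        if t_int > 0.92:
            raise SpecificationError(
                f"np fractions (area {fa}, volume {fv}) need an interior layer "
                f"share {t_int:.2f} beyond the disc footprint; refine mesh_size")
        targets[1:-1] = t_int
    mesh, core = _annular_solid(a, b, h, n_c, n_z, targets, top_dims=top)
    ids = np.arange(mesh.n_elems, dtype=np.int64)
    mesh.elem_sets["NP"] = ids[core]
    mesh.elem_sets["AF"] = ids[~core]
    if spec.quadratic:
        mesh = tet4_to_tet10(mesh)
    return mesh


def generate_spacer(spec: PhantomSpec, height: float,
                    dims: tuple[float, float],
                    top_dims: tuple[float, float] | None = None) -> Mesh:
    """PEEK interbody spacer filling a ground disc space (whole footprint)."""
    a, b = dims[0] / 2.0, dims[1] / 2.0
    top = None if top_dims is None else (top_dims[0] / 2.0, top_dims[1] / 2.0)
    n_c = spec.n_cross()
    n_z = max(2, int(np.ceil(height / spec.mesh_size)))
    mesh, _ = _annular_solid(a, b, height, n_c, n_z, None, top_dims=top)
    mesh.elem_sets["spacer"] = np.arange(mesh.n_elems, dtype=np.int64)
    if spec.quadratic:
        mesh = tet4_to_tet10(mesh)
    return mesh


# ----------------------------------------------------------------------
# NP share measurement (used by tests and the acceptance surface)


def disc_np_shares(mesh: Mesh) -> tuple[float, float]:
    """(endplate-area share, volume share) of the NP set of a disc mesh."""
    vols = mesh.element_volumes()
    np_ids = set(int(i) for i in mesh.elem_sets["NP"])
    v_np = sum(vols[i] for i in np_ids)
    v_all = float(vols.sum())
    # area share on the inferior endplate: bottom faces of bottom-layer tets
    zmin = mesh.nodes[:, 2].min()
    area_np = area_all = 0.0
    for eid, kind, conn in mesh.iter_elements():
        if kind not in ("tet4", "tet10"):
            continue
        for fa in TET_FACES:
            tri = conn[list(fa)]
            x = mesh.nodes[tri]
            if np.all(np.abs(x[:, 2] - zmin) < 1e-9):
                area = 0.5 * np.linalg.norm(np.cross(x[1] - x[0], x[2] - x[0]))
                area_all += area
                if eid in np_ids:
                    area_np += area
    return area_np / area_all, v_np / v_all


# ----------------------------------------------------------------------
# interpolated connections (surface projection / volumetric embedding)


def _surface_mpcs(model: Model, slave_ids, patch_name: str) -> None:
    """Tie each slave node to its closest master-surface triangle with
    barycentric interpolation weights (no spurious tie couples)."""
    from .fem import _closest_point_triangle

    mesh = model.mesh
    patch = mesh.surfaces[patch_name]
    tris = surface_triangles(mesh, patch)
    for s in slave_ids:
        p = mesh.nodes[int(s)]
        best = None
        for tri in tris:
            a, b, c = mesh.nodes[tri]
            q = _closest_point_triangle(p, a, b, c)
            d = np.linalg.norm(p - q)
            if best is None or d < best[0]:
                best = (d, tri, q)
        _d, tri, q = best
        a, b, c = mesh.nodes[tri]
        T = np.column_stack([b - a, c - a])
        uv, *_ = np.linalg.lstsq(T, q - a, rcond=None)
        w = np.clip(np.array([1 - uv[0] - uv[1], uv[0], uv[1]]), 0.0, 1.0)
        w = w / w.sum()
        model.mpcs.append(Mpc(int(s), tri.astype(np.int64), w))


def _washer_bonds(model: Model, slave_ids, patch_name: str,
                  area: float = 2.0) -> None:
    """Bond each slave node to the corners of its closest master-surface
    triangle with short bilateral (compression-capable) titanium trusses.

    Unlike an offset DOF merge or a projection MPC, these are real axial
    elements, so the global force AND moment balance stay exact.  Used for
    the screw's anterior cortical purchase.
    """
    from .fem import _closest_point_triangle

    mesh = model.mesh
    tris = surface_triangles(mesh, mesh.surfaces[patch_name])
    conns = []
    for s in slave_ids:
        p = mesh.nodes[int(s)]
        best = None
        for tri in tris:
            a, b, c = mesh.nodes[tri]
            q = _closest_point_triangle(p, a, b, c)
            d = np.linalg.norm(p - q)
            if best is None or d < best[0]:
                best = (d, tri)
        for m in best[1]:
            if np.linalg.norm(mesh.nodes[int(m)] - p) < 1e-9:
                model.ties.append((int(s), int(m)))
            else:
                conns.append([int(s), int(m)])
    if not conns:
        return
    ne_before = mesh.n_elems
    start, stop = mesh.add_block("truss2", np.array(conns, dtype=np.int64))
    if model.area is None:
        model.area = np.zeros(ne_before)
    elif len(model.area) < ne_before:
        model.area = np.concatenate([model.area,
                                     np.zeros(ne_before - len(model.area))])
    model.area = np.concatenate([model.area, np.full(stop - start, area)])
    if model.tension_only is None:
        model.tension_only = np.ones(ne_before, dtype=bool)
    elif len(model.tension_only) < ne_before:
        model.tension_only = np.concatenate(
            [model.tension_only, np.ones(ne_before - len(model.tension_only), bool)])
    model.tension_only = np.concatenate(
        [model.tension_only, np.zeros(stop - start, dtype=bool)])
    eids = np.arange(start, stop, dtype=np.int64)
    prev = mesh.elem_sets.get("bond_screw", np.array([], dtype=np.int64))
    mesh.elem_sets["bond_screw"] = np.concatenate([prev, eids])


def _embed_mpcs(model: Model, slave_ids, elem_ids, min_bary: float = -0.02
                ) -> np.ndarray:
    """Embed slave nodes in the tet field of the given (host) elements:
    u_slave = barycentric interpolation of the enclosing tet's corners.
    Only (essentially) enclosed nodes are constrained -- the interpolation
    point then coincides with the slave, so the constraint transmits no
    spurious couple.  Returns the slave ids left free (no enclosing host)."""
    from scipy.spatial import cKDTree

    mesh = model.mesh
    elem_ids = np.asarray(elem_ids, dtype=np.int64)
    corners = np.empty((len(elem_ids), 4), dtype=np.int64)
    for k, eid in enumerate(elem_ids):
        _kind, conn = mesh.element(int(eid))
        corners[k] = conn[:4]
    cents = mesh.nodes[corners].mean(axis=1)
    tree = cKDTree(cents)
    unplaced = []
    for s in slave_ids:
        p = mesh.nodes[int(s)]
        _d, cand = tree.query(p, k=min(12, len(elem_ids)))
        cand = np.atleast_1d(cand)
        best = None
        for k in cand:
            x = mesh.nodes[corners[k]]
            T = np.column_stack([x[1] - x[0], x[2] - x[0], x[3] - x[0]])
            try:
                lmb = np.linalg.solve(T, p - x[0])
            except np.linalg.LinAlgError:
                continue
            bary = np.array([1 - lmb.sum(), lmb[0], lmb[1], lmb[2]])
            score = bary.min()
            if best is None or score > best[0]:
                best = (score, k, bary)
            if score >= 0.0:
                break
        if best is None or best[0] < min_bary:
            unplaced.append(int(s))
            continue
        _score, k, bary = best
        w = np.clip(bary, 0.0, 1.0)
        w = w / w.sum()
        model.mpcs.append(Mpc(int(s), corners[k].copy(), w))
    return np.array(unplaced, dtype=np.int64)


# ----------------------------------------------------------------------
# ligaments


def _nearest_in_range(mesh: Mesh, point: np.ndarray, rng: tuple[int, int]) -> int:
    ids = np.arange(rng[0], rng[1])
    d = np.linalg.norm(mesh.nodes[ids] - point, axis=1)
    return int(ids[np.argmin(d)])


def generate_ligaments(model: Model, table: dict | None = None) -> Model:
    """Add one tension-only truss per ligament unit per junction.

    Groups: ALL, PLL, ISL, SSL, ITL (paired), LF (paired).  ALL is omitted
    across the resected span recorded in ``model.meta['all_resected']``; SSL
    is skipped at junctions listed in the spec's ``ssl_merged_junctions``
    (where it is merged with ISL).
    """
    table = table or {g: LIGAMENT_CARDS[g] + (LIGAMENT_UNITS[g],) for g in LIGAMENT_CARDS}
    mesh = model.mesh
    lm = model.meta.get("landmarks")
    ranges = model.meta.get("node_ranges")
    if lm is None or ranges is None:
        raise AssemblyError("model lacks landmark metadata; assemble the spine first")
    resected = set(model.meta.get("all_resected", ()))
    merged_ssl = set(model.meta.get("ssl_merged_junctions", ()))
    levels = model.meta["levels"]

    conns, areas, set_rows = [], [], []
    for up, lo in zip(levels[:-1], levels[1:]):
        junction = f"{up}-{lo}"
        for group, card in table.items():
            if group == "ALL" and junction in resected:
                continue
            if group == "SSL" and junction in merged_ssl:
                continue
            E, nu, area = card[:3]
            units = card[3] if len(card) > 3 else LIGAMENT_UNITS.get(group, 1)
            for unit in range(units):
                side = "left" if (units == 2 and unit == 0) else (
                    "right" if units == 2 else "mid")
                key_u = f"{group.lower()}_inf_{side}"
                key_l = f"{group.lower()}_sup_{side}"
                if key_u not in lm[up] or key_l not in lm[lo]:
                    raise AssemblyError(
                        f"missing landmark for ligament {group} at junction {junction}")
                n_u = _nearest_in_range(mesh, lm[up][key_u], ranges[up])
                n_l = _nearest_in_range(mesh, lm[lo][key_l], ranges[lo])
                conns.append([n_u, n_l])
                areas.append(area / units)
                set_rows.append((group, junction))
    if not conns:
        return model
    start, stop = mesh.add_block("truss2", np.array(conns, dtype=np.int64))
    if model.area is None:
        model.area = np.zeros(start)
    model.area = np.concatenate([model.area, np.asarray(areas)])
    eids = np.arange(start, stop, dtype=np.int64)
    for name in sorted({f"lig_{g}_{j}" for g, j in set_rows} |
                       {f"lig_{g}" for g, _ in set_rows}):
        parts = name.split("_")
        if len(parts) == 2:
            sel = [k for k, (g, _) in enumerate(set_rows) if g == parts[1]]
        else:
            sel = [k for k, (g, j) in enumerate(set_rows)
                   if g == parts[1] and j == parts[2]]
        mesh.elem_sets[name] = eids[sel]
    return model


# ----------------------------------------------------------------------
# instrumentation


def _cylinder_mesh(radius: float, length: float, n_c: int, n_len: int) -> Mesh:
    """Tet cylinder with axis along +y, base at y = 0 (local frame)."""
    m, _ = _annular_solid(radius, radius, length, n_c, n_len, None)
    # rotate: local z (axis) -> y
    xyz = m.nodes.copy()
    m.nodes = np.column_stack([xyz[:, 0], xyz[:, 2], -xyz[:, 1]])
    return m


def generate_instrumentation(model: Model, inst: InstrumentSpec) -> Model:
    """Add spacers, the anterior plate and the screws; bond by node ties.

    The spanned disc spaces must have been left empty (no NP/AF) by
    assembly; spacer solids fill them and tie to the adjacent endplates.
    Screws pass through the plate into the trabecular body and are
    node-equivalenced with coincident/nearby bone and plate nodes.  Per
    screw, the element set ``trajectory_<level>_<side>`` collects bone
    elements within one screw diameter of the shaft axis.
    """
    spec: PhantomSpec = model.meta["spec"]
    mesh = model.mesh
    z_of = model.meta["z_offsets"]          # level -> body inferior z
    ranges = model.meta["node_ranges"]
    for lv in inst.plate_span:
        if lv not in z_of:
            raise AssemblyError(f"plate_span level {lv} not in assembled model")

    # ---- spacers ----
    n_spacers = 0
    for junction, height in zip(inst.spanned_junctions, inst.spacer_heights):
        up, lo = junction.split("-")
        wu, du, _ = spec.dims(up)
        wl, dl, _ = spec.dims(lo)
        sp_mesh = generate_spacer(spec, height, (wl, dl), top_dims=(wu, du))
        z_bot = z_of[lo] + spec.dims(lo)[2]
        sp_mesh.nodes[:, 2] += z_bot
        noff, _eoff = mesh.merge(sp_mesh, prefix=f"tmp{junction}_")
        mesh.elem_sets[f"spacer_{junction}"] = mesh.elem_sets.pop(f"tmp{junction}_spacer")
        sup = mesh.node_sets.pop(f"tmp{junction}_sup")
        inf = mesh.node_sets.pop(f"tmp{junction}_inf")
        model.ties += nearest_node_pairs(
            mesh.nodes, inf, mesh.nodes,
            mesh.node_sets[f"endplate_sup_{lo}"], 1e-6)
        model.ties += nearest_node_pairs(
            mesh.nodes, sup, mesh.nodes,
            mesh.node_sets[f"endplate_inf_{up}"], 1e-6)
        n_spacers += 1

    # ---- plate ----
    bmax = max(spec.dims(lv)[1] for lv in inst.plate_span) / 2.0
    y_in = -(bmax + inst.plate_standoff)          # posterior plate face
    z_lo_span = z_of[inst.plate_span[-1]]
    z_hi_span = z_of[inst.plate_span[0]] + spec.dims(inst.plate_span[0])[2]
    z_mid = 0.5 * (z_lo_span + z_hi_span)
    z_plate0 = z_mid - inst.plate_length / 2.0
    pl = box_mesh(inst.plate_width, inst.plate_thickness, inst.plate_length,
                  max(3, int(np.ceil(inst.plate_width / spec.mesh_size))), 1,
                  max(6, int(np.ceil(inst.plate_length / spec.mesh_size))),
                  origin=(-inst.plate_width / 2.0, y_in - inst.plate_thickness, z_plate0))
    if spec.quadratic:
        pl = tet4_to_tet10(pl)
    _noff, eoff = mesh.merge(pl, prefix="plate_")
    for junk in list(mesh.node_sets):
        if junk.startswith("plate_"):
            mesh.node_sets.pop(junk)
    plate_eids = np.arange(eoff, mesh.n_elems, dtype=np.int64)
    mesh.elem_sets["plate"] = plate_eids
    plate_nodes = np.unique(np.concatenate(
        [mesh.element(int(e))[1] for e in plate_eids]))

    # ---- screws ----
    r = inst.screw_diameter / 2.0
    min_gap = 0.2
    screw_axes = {}
    for lv in inst.plate_span:
        w, d, h = spec.dims(lv)
        a, b = w / 2.0, d / 2.0
        z_c = z_of[lv] + h / 2.0
        z_c = min(max(z_c, z_plate0 + 2.0), z_plate0 + inst.plate_length - 2.0)
        for side, sgn in (("left", -1.0), ("right", 1.0)):
            x_c = sgn * 0.25 * w
            y_start = y_in - inst.plate_thickness
            y_tip = y_start + inst.screw_length
            y_wall = b * np.sqrt(max(0.0, 1.0 - (x_c / a) ** 2))
            if y_tip > y_wall - min_gap:
                raise GeometryError(
                    f"screw at {lv}/{side} (length {inst.screw_length} mm) exits the "
                    f"body: tip y={y_tip:.2f} vs posterior wall y={y_wall:.2f}")
            sc = _cylinder_mesh(r, inst.screw_length, 2,
                                max(3, int(np.ceil(inst.screw_length / spec.mesh_size))))
            sc.node_sets.clear()
            if spec.quadratic:
                sc = tet4_to_tet10(sc)
            sc.nodes += np.array([x_c, y_start, z_c])
            noff, eoff = mesh.merge(sc, prefix=f"screw_{lv}_{side}_")
            mesh.elem_sets[f"screw_{lv}_{side}"] = np.arange(eoff, mesh.n_elems,
                                                             dtype=np.int64)
            screw_nodes = np.arange(noff, mesh.n_nodes, dtype=np.int64)
            # bond by embedding: screw nodes follow the interpolated
            # displacement field of their host solid (plate in the head
            # region, trabecular bone along the shaft), reinforcing it
            in_plate = screw_nodes[mesh.nodes[screw_nodes, 1] <= y_in + 1e-9]
            in_bone = screw_nodes[mesh.nodes[screw_nodes, 1] > y_in + 1e-9]
            _embed_mpcs(model, in_plate, plate_eids)
            bone_eids = np.concatenate([mesh.elem_sets[f"central_body_{lv}"],
                                        mesh.elem_sets[f"exterior_body_{lv}"]])
            at_wall = _embed_mpcs(model, in_bone, bone_eids)
            # entry-zone nodes sit in the gap between plate and the curved
            # anterior wall: bond them to the cortical wall with short
            # bilateral struts (anterior cortical purchase of the screw)
            at_wall = at_wall[mesh.nodes[at_wall, 1] < 0.0]
            if len(at_wall):
                _washer_bonds(model, at_wall, f"body_lateral_{lv}")
            screw_axes[(lv, side)] = (x_c, z_c, y_start, y_tip)

    # ---- trajectory sets ----
    cents = mesh.element_centroids()
    for (lv, side), (x_c, z_c, y_s, y_t) in screw_axes.items():
        bone = np.concatenate([mesh.elem_sets[f"central_body_{lv}"],
                               mesh.elem_sets[f"exterior_body_{lv}"]])
        c = cents[bone]
        radial = np.sqrt((c[:, 0] - x_c) ** 2 + (c[:, 2] - z_c) ** 2)
        near = bone[(radial <= inst.screw_diameter) & (c[:, 1] >= y_s) & (c[:, 1] <= y_t)]
        if len(near) == 0:
            raise AssemblyError(f"empty trajectory set at {lv}/{side}")
        mesh.elem_sets[f"trajectory_{lv}_{side}"] = np.sort(near)
    model.meta["screw_axes"] = screw_axes
    model.meta["n_spacers"] = n_spacers
    model.meta["instrument"] = inst
    return model


# ----------------------------------------------------------------------
# full assembly


def assemble_spine(spec: PhantomSpec | None = None,
                   inst: InstrumentSpec | None = None) -> Model:
    """Full C2-T2 model: vertebrae, discs/spacers, ligaments, instruments,
    facet contact pairs (C5-C6 .. T1-T2, friction 0.07), base fixation sets
    and the C2 kinematic coupling.  Deterministic for a fixed spec seed.
    """
    spec = spec or PhantomSpec()
    levels = list(spec.levels)
    spanned = set(inst.spanned_junctions) if inst else set()

    # junction gaps (instrumented junctions take the spacer height)
    gaps: dict[str, float] = {}
    for j in spec.junctions:
        gaps[j] = spec.disc_height
    if inst:
        for j, hgt in zip(inst.spanned_junctions, inst.spacer_heights):
            gaps[j] = hgt

    # z layout bottom-up (last level at z = 0)
    z_of: dict[str, float] = {}
    z = 0.0
    for lv_lo, lv_up in zip(levels[::-1][:-1], levels[::-1][1:]):
        z_of[lv_lo] = z
        z += spec.dims(lv_lo)[2] + gaps[f"{lv_up}-{lv_lo}"]
    z_of[levels[0]] = z

    mesh = Mesh(np.zeros((0, 3)))
    model = Model(mesh=mesh)
    ranges: dict[str, tuple[int, int]] = {}
    landmarks: dict[str, dict[str, np.ndarray]] = {}

    contact_set = set(CONTACT_JUNCTIONS) & set(spec.junctions)
    for lv in levels:
        i = levels.index(lv)
        j_above = f"{levels[i - 1]}-{lv}" if i > 0 else None
        j_below = f"{lv}-{levels[i + 1]}" if i < len(levels) - 1 else None
        ext_sup = ((gaps[j_above] - spec.facet_gap) / 2.0
                   if j_above in contact_set else 0.0)
        ext_inf = ((gaps[j_below] - spec.facet_gap) / 2.0
                   if j_below in contact_set else 0.0)
        vm = generate_vertebra(spec, lv, extend_sup=ext_sup, extend_inf=ext_inf)
        vm.nodes[:, 2] += z_of[lv]
        n0 = mesh.n_nodes
        mesh.merge(vm, prefix=f"tmp_")
        ranges[lv] = (n0, mesh.n_nodes)
        for base in list(mesh.elem_sets):
            if base.startswith("tmp_"):
                mesh.elem_sets[base[4:] + f"_{lv}"] = mesh.elem_sets.pop(base)
        for base in list(mesh.node_sets):
            if base.startswith("tmp_"):
                mesh.node_sets[base[4:] + f"_{lv}"] = mesh.node_sets.pop(base)
        for base in list(mesh.surfaces):
            if base.startswith("tmp_"):
                mesh.surfaces[base[4:] + f"_{lv}"] = mesh.surfaces.pop(base)
        mesh.node_sets[f"vert_{lv}"] = np.arange(n0, mesh.n_nodes, dtype=np.int64)
        # bond the posterior block to the body by volumetric embedding of
        # its anterior face (which lies inside the body ellipse)
        host = np.concatenate([mesh.elem_sets[f"central_body_{lv}"],
                               mesh.elem_sets[f"exterior_body_{lv}"]])
        free = _embed_mpcs(model, mesh.node_sets[f"blk_anterior_{lv}"], host)
        if len(free) > len(mesh.node_sets[f"blk_anterior_{lv}"]) // 2:
            raise AssemblyError(
                f"{lv}: posterior block anchoring failed ({len(free)} nodes "
                "found no enclosing body element)")
        # landmarks for ligament attachment
        w, d, h = spec.dims(lv)
        a, b = w / 2.0, d / 2.0
        z0, z1 = z_of[lv], z_of[lv] + h
        y_tip = 0.80 * b + 0.75 * d
        y_lam = 0.80 * b + 0.1 * d
        wb = 0.5 * w
        landmarks[lv] = {
            "all_sup_mid": np.array([0.0, -b, z1]),
            "all_inf_mid": np.array([0.0, -b, z0]),
            "pll_sup_mid": np.array([0.0, b, z1]),
            "pll_inf_mid": np.array([0.0, b, z0]),
            "isl_sup_mid": np.array([0.0, 0.80 * b + 0.4 * d, z1]),
            "isl_inf_mid": np.array([0.0, 0.80 * b + 0.4 * d, z0]),
            "ssl_sup_mid": np.array([0.0, y_tip, z1]),
            "ssl_inf_mid": np.array([0.0, y_tip, z0]),
            "itl_sup_left": np.array([-a, 0.0, z1]),
            "itl_inf_left": np.array([-a, 0.0, z0]),
            "itl_sup_right": np.array([a, 0.0, z1]),
            "itl_inf_right": np.array([a, 0.0, z0]),
            "lf_sup_left": np.array([-wb / 4.0, y_lam, z1]),
            "lf_inf_left": np.array([-wb / 4.0, y_lam, z0]),
            "lf_sup_right": np.array([wb / 4.0, y_lam, z1]),
            "lf_inf_right": np.array([wb / 4.0, y_lam, z0]),
        }

    # aggregate trabecular sets
    for agg in ("central_body", "exterior_body", "cortical"):
        mesh.elem_sets[agg] = np.concatenate(
            [mesh.elem_sets[f"{agg}_{lv}"] for lv in levels])

    # discs at non-instrumented junctions
    for j in spec.junctions:
        if j in spanned:
            continue
        up, lo = j.split("-")
        dm = generate_disc(spec, j, height=gaps[j])
        dm.nodes[:, 2] += z_of[lo] + spec.dims(lo)[2]
        mesh.merge(dm, prefix=f"tmpd_")
        for base, new in (("NP", f"NP_{j}"), ("AF", f"AF_{j}")):
            mesh.elem_sets[new] = mesh.elem_sets.pop(f"tmpd_{base}")
        sup = mesh.node_sets.pop("tmpd_sup")
        inf = mesh.node_sets.pop("tmpd_inf")
        model.ties += nearest_node_pairs(mesh.nodes, inf, mesh.nodes,
                                         mesh.node_sets[f"endplate_sup_{lo}"],
                                         1e-6)
        model.ties += nearest_node_pairs(mesh.nodes, sup, mesh.nodes,
                                         mesh.node_sets[f"endplate_inf_{up}"],
                                         1e-6)

    model.meta.update({
        "spec": spec,
        "levels": levels,
        "z_offsets": z_of,
        "node_ranges": ranges,
        "landmarks": landmarks,
        "junction_gaps": gaps,
        "friction": 0.07,
        "all_resected": tuple(inst.all_resected_span) if inst else (),
        "ssl_merged_junctions": tuple(spec.ssl_merged_junctions),
    })

    generate_ligaments(model)
    if inst:
        generate_instrumentation(model, inst)
        # bone elements adjacent to the spacer-tied endplates (for verdicts)
        for j in inst.spanned_junctions:
            up, lo = j.split("-")
            touched = []
            for lv, ep in ((up, f"endplate_inf_{up}"), (lo, f"endplate_sup_{lo}")):
                epn = set(int(n) for n in mesh.node_sets[ep])
                for eid in np.concatenate([mesh.elem_sets[f"central_body_{lv}"],
                                           mesh.elem_sets[f"exterior_body_{lv}"]]):
                    _k, conn = mesh.element(int(eid))
                    if any(int(n) in epn for n in conn):
                        touched.append(int(eid))
            mesh.elem_sets[f"endplate_contact_{j}"] = np.array(sorted(set(touched)),
                                                               dtype=np.int64)

    # facet contact pairs
    for j in sorted(contact_set, key=JUNCTIONS.index):
        up, lo = j.split("-")
        model.contacts.append(ContactPair(
            name=j, master_surface=f"facet_sup_{lo}",
            slave_set=f"facet_inf_nodes_{up}", friction=0.07))

    # base fixation sets (default: inferior-most level)
    for lv in levels:
        base = np.unique(np.concatenate([mesh.node_sets[f"endplate_inf_{lv}"],
                                         mesh.node_sets[f"facet_inf_nodes_{lv}"]]))
        mesh.node_sets[f"base_{lv}"] = base
    mesh.node_sets["base"] = mesh.node_sets[f"base_{levels[-1]}"]

    # C2 loading sets and kinematic coupling
    if "odontoid_facet_left_C2" in mesh.node_sets:
        mesh.node_sets["c2_facet_left"] = mesh.node_sets["odontoid_facet_left_C2"]
        mesh.node_sets["c2_facet_right"] = mesh.node_sets["odontoid_facet_right_C2"]
        spin = mesh.node_sets["spinous_C2"]
        model.couplings["c2_spinous"] = Coupling(
            ref_point=mesh.nodes[spin].mean(axis=0), node_set="spinous_C2")

    # truss areas default 0 for solids (generate_ligaments already extended)
    if model.area is None:
        model.area = np.zeros(mesh.n_elems)
    elif len(model.area) < mesh.n_elems:
        model.area = np.concatenate(
            [model.area, np.zeros(mesh.n_elems - len(model.area))])
    if model.tension_only is None:
        model.tension_only = np.ones(mesh.n_elems, dtype=bool)
    elif len(model.tension_only) < mesh.n_elems:
        model.tension_only = np.concatenate(
            [model.tension_only,
             np.ones(mesh.n_elems - len(model.tension_only), dtype=bool)])
    return model
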