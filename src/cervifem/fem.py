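"""Linear elastostatic core: constraints, assembly, outer-loop solve.

Constraint handling follows the node-equivalence philosophy: tied node
pairs share degrees of freedom outright (union-find DOF merging), and each
kinematic coupling condenses a follower node set onto a 6-DOF reference
point (u_i = u_ref + theta x r_i).  Both are expressed through one sparse
reduction matrix C with  u_full = C u_red,  K_red = C^T K C.

Tension-only ligament trusses and small-sliding penalty contact make the
problem mildly nonlinear; both are resolved by an outer fixed-point loop
over active sets around the linear solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elements import (element_stiffness_solid, element_stiffness_truss,
                       element_strain_solid, truss_axial_strain)
from .mesh import Mesh, merge_pairs_map, surface_triangles

log = logging.getLogger(__name__)


class FemError(RuntimeError):
    """Raised for singular systems, non-convergence, or contact failure."""


@dataclass
class Coupling:
    """Kinematic coupling: a 6-DOF reference point rigidly driving a node set."""

    ref_point: np.ndarray
    node_set: str


@dataclass
class ContactPair:
    """Small-sliding node-to-surface penalty contact with Coulomb friction."""

    name: str
    master_surface: str
    slave_set: str
    friction: float = 0.07
    penalty: float | None = None  # N/mm per slave node; derived if None


@dataclass
class Mpc:
    """Linear multi-point constraint: u_slave = sum_i w_i u_master_i.

    Unlike a raw DOF merge of offset nodes, the interpolated constraint
    transmits force through the master points at (nearly) the slave's own
    location, so no spurious couples appear in the global moment balance.
    """

    slave: int
    masters: np.ndarray
    weights: np.ndarray


@dataclass
class Model:
    """Assembled mesh + named sets + materials + constraints + contact."""

    mesh: Mesh
    E: np.ndarray | None = None
    nu: np.ndarray | None = None
    area: np.ndarray | None = None          # truss cross-sections (mm^2)
    tension_only: np.ndarray | None = None  # per-element flag (default: all trusses)
    ties: list[tuple[int, int]] = field(default_factory=list)
    mpcs: list[Mpc] = field(default_factory=list)
    couplings: dict[str, Coupling] = field(default_factory=dict)
    contacts: list[ContactPair] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def clear_cache(self) -> None:
        """Drop cached assemblies (call after mutating mesh or materials)."""
        self._cache.clear()


@dataclass
class SolveOptions:
    rtol: float = 1e-8
    contact_rtol: float = 1e-5       # settle tol for the regularized friction state
    friction_passes: int = 3         # secant Coulomb updates before freezing
    max_outer: int = 50
    penalty_factor: float = 50.0     # x representative master stiffness
    penetration_tol: float = 1e-3    # mm allowed at convergence


@dataclass
class SolveResult:
    """Displacements, per-element strain, truss/contact state of one solve."""

    u: np.ndarray                    # (nn, 3) mm
    strain: np.ndarray               # (ne, 6) engineering strain (solids)
    truss_axial: np.ndarray          # (ne,) axial strain, nan for non-truss
    truss_active: np.ndarray         # (ne,) bool, tension-active trusses
    slips: dict[str, np.ndarray]     # contact name -> per-slave slip (mm)
    contact_active: dict[str, np.ndarray]
    n_outer: int = 1
    energy_ratio: float = 1.0        # u^T K u / f^T u at convergence
    f_ext: np.ndarray | None = None


# ----------------------------------------------------------------------
# constraint reduction


@dataclass
class Reduction:
    C: sp.csr_matrix                 # (nfull, nred)
    nn: int
    coupling_names: list[str]
    ref_start: dict[str, int]        # coupling -> first of its 6 full dofs
    nred: int


def build_reduction(model: Model, fixed_set: str) -> Reduction:
    """Build the u_full = C u_red map for ties, MPCs, couplings and fixed
    DOFs.  Resolution order: exact-merge ties first (union-find), then
    coupling followers, then fixed DOFs, then interpolated MPC slaves
    (whose masters must themselves be plain/tied/follower nodes)."""
    mesh = model.mesh
    nn = mesh.n_nodes
    rep = merge_pairs_map(nn, model.ties)
    names = sorted(model.couplings)
    nfull = 3 * nn + 6 * len(names)

    follower: dict[int, int] = {}
    for ci, name in enumerate(names):
        cp = model.couplings[name]
        if cp.node_set not in mesh.node_sets:
            raise FemError(f"coupling {name!r}: node set {cp.node_set!r} missing")
        for nid in mesh.node_sets[cp.node_set]:
            follower[int(rep[nid])] = ci
    if fixed_set not in mesh.node_sets:
        raise FemError(f"fixed node set {fixed_set!r} missing")
    fixed = {int(rep[i]) for i in mesh.node_sets[fixed_set]}
    clash = fixed & set(follower)
    if clash:
        raise FemError(f"{len(clash)} nodes are both fixed and coupling followers")

    # MPC slaves: dropped if their node ended up fixed; a slave must not be
    # the master of another constraint class
    slaves: dict[int, Mpc] = {}
    for mpc in model.mpcs:
        s = int(rep[mpc.slave])
        if s in fixed:
            continue
        if s in follower:
            raise FemError(f"MPC slave {mpc.slave} is also a coupling follower")
        slaves[s] = mpc
    for mpc in slaves.values():
        for m in mpc.masters:
            if int(rep[m]) in slaves:
                raise FemError(f"MPC master {int(m)} is itself an MPC slave")

    red_of_rep = np.full(nn, -1, dtype=np.int64)
    nred = 0
    for i in range(nn):
        if rep[i] == i and i not in follower and i not in fixed and i not in slaves:
            red_of_rep[i] = nred
            nred += 3
    ref_red = {}
    for ci, name in enumerate(names):
        ref_red[name] = nred + 6 * ci
    nred_total = nred + 6 * len(names)

    def dof_cols(node: int, a: int) -> list[tuple[int, float]]:
        """Reduced-space expansion of full dof (node, a) for non-slave nodes."""
        r = int(rep[node])
        if r in fixed:
            return []
        if r in follower:
            name = names[follower[r]]
            start = ref_red[name]
            rx, ry, rz = mesh.nodes[r] - model.couplings[name].ref_point
            out = [(start + a, 1.0)]
            if a == 0:
                out += [(start + 4, rz), (start + 5, -ry)]
            elif a == 1:
                out += [(start + 5, rx), (start + 3, -rz)]
            else:
                out += [(start + 3, ry), (start + 4, -rx)]
            return out
        return [(int(red_of_rep[r]) + a, 1.0)]

    rows, cols, vals = [], [], []
    for i in range(nn):
        r = int(rep[i])
        if r in slaves:
            mpc = slaves[r]
            for a in range(3):
                acc: dict[int, float] = {}
                for m, w in zip(mpc.masters, mpc.weights):
                    for col, v in dof_cols(int(m), a):
                        acc[col] = acc.get(col, 0.0) + w * v
                for col, v in acc.items():
                    rows.append(3 * i + a)
                    cols.append(col)
                    vals.append(v)
            continue
        for a in range(3):
            for col, v in dof_cols(i, a):
                rows.append(3 * i + a)
                cols.append(col)
                vals.append(v)
    ref_start_full = {}
    for ci, name in enumerate(names):
        fs = 3 * nn + 6 * ci
        ref_start_full[name] = fs
        for a in range(6):
            rows.append(fs + a)
            cols.append(ref_red[name] + a)
            vals.append(1.0)
    C = sp.coo_matrix((vals, (rows, cols)), shape=(nfull, nred_total)).tocsr()
    return Reduction(C=C, nn=nn, coupling_names=names,
                     ref_start=ref_start_full, nred=nred_total)


# ----------------------------------------------------------------------
# assembly


def _scatter(rows, cols, vals, conn, Ke):
    dofs = np.empty(3 * len(conn), dtype=np.int64)
    for a, nid in enumerate(conn):
        dofs[3 * a:3 * a + 3] = (3 * nid, 3 * nid + 1, 3 * nid + 2)
    ii, jj = np.meshgrid(dofs, dofs, indexing="ij")
    rows.append(ii.ravel())
    cols.append(jj.ravel())
    vals.append(Ke.ravel())


def assemble_solids(model: Model) -> sp.csr_matrix:
    """Global stiffness of all solid elements on node DOFs (3*nn)."""
    mesh = model.mesh
    if model.E is None or model.nu is None:
        raise FemError("materials not assigned")
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for eid, kind, conn in mesh.iter_elements():
        if kind == "truss2":
            continue
        Ke = element_stiffness_solid(mesh.nodes[conn], model.E[eid], model.nu[eid], kind)
        _scatter(rows, cols, vals, conn, Ke)
    n = 3 * mesh.n_nodes
    if not rows:
        return sp.csr_matrix((n, n))
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    return K


def _truss_elements(model: Model) -> list[tuple[int, np.ndarray]]:
    """Cached (eid, conn) list of all truss elements."""
    if "trusses" not in model._cache:
        model._cache["trusses"] = [
            (eid, conn.copy()) for eid, kind, conn in model.mesh.iter_elements()
            if kind == "truss2"]
    return model._cache["trusses"]


def assemble_trusses(model: Model, active: np.ndarray) -> sp.csr_matrix:
    """Stiffness of the currently tension-active trusses on node DOFs."""
    mesh = model.mesh
    rows, cols, vals = [], [], []
    for eid, conn in _truss_elements(model):
        if not active[eid]:
            continue
        Ke = element_stiffness_truss(mesh.nodes[conn], model.E[eid], model.area[eid])
        _scatter(rows, cols, vals, conn, Ke)
    n = 3 * mesh.n_nodes
    if not rows:
        return sp.csr_matrix((n, n))
    return sp.coo_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n)).tocsr()


def assemble(model: Model, load_case, options: SolveOptions | None = None):
    """Assemble the reduced system (K_red, f_red, reduction) for a load case.

    All trusses are taken tension-active and contact inactive (the starting
    point of the outer loop); K_red is symmetric positive definite once the
    base set is fixed and the structure is connected.
    """
    options = options or SolveOptions()
    red = build_reduction(model, load_case.fixed_set)
    K_node = assemble_solids(model)
    active = _initial_truss_active(model)
    K_node = K_node + assemble_trusses(model, active)
    C_node = red.C[:3 * model.mesh.n_nodes, :]
    K_red = (C_node.T @ K_node @ C_node).tocsr()
    f_red = red.C.T @ _full_load_vector(model, load_case, red)
    return K_red, f_red, red


def _initial_truss_active(model: Model) -> np.ndarray:
    active = np.zeros(model.mesh.n_elems, dtype=bool)
    for eid, kind, _ in model.mesh.iter_elements():
        if kind == "truss2":
            active[eid] = True
    return active


def _full_load_vector(model: Model, load_case, red: Reduction) -> np.ndarray:
    f = np.zeros(red.C.shape[0])
    for nid, vec in load_case.nodal_forces(model).items():
        f[3 * nid:3 * nid + 3] += vec
    coupling = getattr(load_case, "coupling", None)
    torque = np.asarray(getattr(load_case, "torque", np.zeros(3)))
    if coupling is not None and np.any(torque):
        start = red.ref_start[coupling]
        f[start + 3:start + 6] += torque
    return f


# ----------------------------------------------------------------------
# contact machinery


def _closest_point_triangle(p, a, b, c):
    """Closest point on triangle abc to p (Ericson's algorithm)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        v = d1 / (d1 - d3)
        return a + v * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        w = d2 / (d2 - d6)
        return a + w * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + ab * v + ac * w


@dataclass
class _PairState:
    """One slave node paired (once, small-sliding) to a master triangle."""

    slave: int
    tri: np.ndarray                  # 3 master node ids
    weights: np.ndarray              # barycentric at initial projection
    normal: np.ndarray               # outward master normal
    gap0: float                      # initial geometric gap
    penalty: float                   # N/mm
    master_elem: int


def _build_contact_pairs(model: Model, contact: ContactPair) -> list[_PairState]:
    mesh = model.mesh
    if contact.master_surface not in mesh.surfaces:
        raise FemError(f"contact {contact.name!r}: master surface missing")
    if contact.slave_set not in mesh.node_sets:
        raise FemError(f"contact {contact.name!r}: slave node set missing")
    patch = mesh.surfaces[contact.master_surface]
    tris = surface_triangles(mesh, patch)
    states = []
    for slave in mesh.node_sets[contact.slave_set]:
        p = mesh.nodes[int(slave)]
        best = None
        for (eid, _f), tri in zip(patch, tris):
            a, b, c = mesh.nodes[tri]
            q = _closest_point_triangle(p, a, b, c)
            d = np.linalg.norm(p - q)
            if best is None or d < best[0]:
                best = (d, tri, q, int(eid))
        d, tri, q, master_eid = best
        a, b, c = mesh.nodes[tri]
        n = np.cross(b - a, c - a)
        n = n / np.linalg.norm(n)
        gap0 = float((p - q) @ n)
        if gap0 < 0:
            n, gap0 = -n, -gap0
        # barycentric weights of q
        T = np.column_stack([b - a, c - a])
        try:
            uv, *_ = np.linalg.lstsq(T, q - a, rcond=None)
        except np.linalg.LinAlgError:
            uv = np.array([1 / 3, 1 / 3])
        w = np.array([1 - uv[0] - uv[1], uv[0], uv[1]])
        w = np.clip(w, 0, 1)
        w = w / w.sum()
        if contact.penalty is not None:
            k_pen = contact.penalty
        else:
            area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            E_m = float(model.E[master_eid]) if model.E is not None else 1000.0
            k_pen = 50.0 * E_m * np.sqrt(area)
        states.append(_PairState(slave=int(slave), tri=tri, weights=w, normal=n,
                                 gap0=gap0, penalty=k_pen, master_elem=master_eid))
    return states


def _contact_relative_disp(state: _PairState, u: np.ndarray) -> np.ndarray:
    um = state.weights @ u[state.tri]
    return u[state.slave] - um


def _contact_system(model: Model, all_states: dict[str, list[_PairState]],
                    active: dict[str, np.ndarray], u: np.ndarray | None,
                    mu: dict[str, float],
                    kt_frozen: dict | None = None):
    """Stiffness and force of the active contact springs on node DOFs.

    Normal penalty spring (anchored at the geometric gap) + secant-
    regularized Coulomb friction: tangential stick springs of stiffness k_n,
    capped to mu*N/|s| once the stick force would exceed the Coulomb limit,
    so at equilibrium a slipping pair carries exactly |F_t| = mu*N opposing
    the slip.  All terms are springs, which keeps the outer fixed point
    stable under relaxation.  ``kt_frozen`` pins the tangential secants of
    known pairs (used once the configured friction passes are exhausted).

    Returns (K_contact, f_contact, kt_used).
    """
    n = 3 * model.mesh.n_nodes
    rows, cols, vals = [], [], []
    f = np.zeros(n)
    kt_used: dict = {}
    for cname, states in all_states.items():
        act = active[cname]
        for k, st in enumerate(states):
            if not act[k]:
                continue
            dofs = np.concatenate([[3 * st.slave, 3 * st.slave + 1, 3 * st.slave + 2]] +
                                  [[3 * m, 3 * m + 1, 3 * m + 2] for m in st.tri])
            # relative-displacement operator: u_rel = G @ u_dofs (3 x 12)
            G = np.zeros((3, 12))
            G[:, :3] = np.eye(3)
            for j in range(3):
                G[:, 3 * (j + 1):3 * (j + 2)] = -st.weights[j] * np.eye(3)
            nvec = st.normal
            a_n = nvec @ G                      # normal gap operator (12,)
            k_n = st.penalty
            Kc = k_n * np.outer(a_n, a_n)
            # tangent frame
            t1 = np.cross(nvec, [1.0, 0, 0])
            if np.linalg.norm(t1) < 1e-6:
                t1 = np.cross(nvec, [0, 1.0, 0])
            t1 = t1 / np.linalg.norm(t1)
            t2 = np.cross(nvec, t1)
            if kt_frozen is not None and (cname, k) in kt_frozen:
                k_t = kt_frozen[(cname, k)]
            else:
                k_t = k_n
                if u is not None:
                    urel = _contact_relative_disp(st, u)
                    g = st.gap0 + urel @ nvec
                    N = max(0.0, -k_n * g)
                    s = np.hypot(urel @ t1, urel @ t2)
                    if k_n * s > mu[cname] * N and s > 1e-12:
                        k_t = mu[cname] * N / s     # secant Coulomb cap
            kt_used[(cname, k)] = k_t
            for t in (t1, t2):
                a_t = t @ G
                Kc = Kc + k_t * np.outer(a_t, a_t)
            # initial-gap preload on the normal spring: f = -k*g0 * a_n
            f[dofs] += -k_n * st.gap0 * a_n
            ii, jj = np.meshgrid(dofs, dofs, indexing="ij")
            rows.append(ii.ravel())
            cols.append(jj.ravel())
            vals.append(Kc.ravel())
    if rows:
        Kc_mat = sp.coo_matrix((np.concatenate(vals),
                                (np.concatenate(rows), np.concatenate(cols))),
                               shape=(n, n)).tocsr()
    else:
        Kc_mat = sp.csr_matrix((n, n))
    return Kc_mat, f, kt_used


# ----------------------------------------------------------------------
# solve


def _factor_solve(K_red: sp.csr_matrix, f_red: np.ndarray) -> np.ndarray:
    """Sparse direct solve (SuperLU symmetric mode + iterative refinement),
    falling back to plain LU, then minres, for degenerate toy systems."""
    K_csc = K_red.tocsc()
    fnorm = np.linalg.norm(f_red)
    for attempt in ("symmetric", "plain"):
        try:
            if attempt == "symmetric":
                lu = spla.splu(K_csc, permc_spec="MMD_AT_PLUS_A",
                               options={"SymmetricMode": True,
                                        "DiagPivotThresh": 0.01})
            else:
                lu = spla.splu(K_csc)
            u = lu.solve(f_red)
            for _ in range(2):  # iterative refinement
                r = f_red - K_red @ u
                if fnorm == 0 or np.linalg.norm(r) <= 1e-10 * fnorm:
                    break
                u = u + lu.solve(r)
            resid = np.linalg.norm(K_red @ u - f_red)
            if fnorm == 0 or resid / fnorm <= 1e-6:
                return u
        except RuntimeError:
            continue
    log.warning("sparse direct factorization failed or inaccurate; trying minres")
    u, info = spla.minres(K_red, f_red, rtol=1e-10, maxiter=20000)
    if info != 0:
        raise FemError("linear solve failed: system singular or ill-posed")
    resid = np.linalg.norm(K_red @ u - f_red)
    if fnorm > 0 and resid / fnorm > 1e-6:
        raise FemError(
            f"linear solve residual {resid / fnorm:.2e}: free-floating component? "
            "check ties/fixations")
    return u


def solve_static(model: Model, load_case, options: SolveOptions | None = None) -> SolveResult:
    """Outer fixed-point loop over truss tension state and contact status.

    Each iteration solves the linear system with the current active sets,
    then (i) deactivates trusses in compression / reactivates those back in
    tension, (ii) updates the contact active set and Coulomb stick/slip
    state on the fixed small-sliding pairing.  Converged when both active
    sets are unchanged and the displacement increment is below ``rtol``
    (relative).
    """
    options = options or SolveOptions()
    mesh = model.mesh
    red = build_reduction(model, load_case.fixed_set)
    if "K_solid" not in model._cache:
        model._cache["K_solid"] = assemble_solids(model)
    K_solid = model._cache["K_solid"]
    nfull = red.C.shape[0]
    n_node_dof = 3 * mesh.n_nodes

    C_node = red.C[:n_node_dof, :]  # ref-point rows carry no stiffness
    K_solid_red = (C_node.T @ K_solid @ C_node).tocsr()

    def reduce_delta(K_delta: sp.spmatrix) -> sp.csr_matrix:
        return (C_node.T @ K_delta @ C_node).tocsr()

    f_full = _full_load_vector(model, load_case, red)
    truss_active = _initial_truss_active(model)

    contact_states = {c.name: _build_contact_pairs(model, c) for c in model.contacts}
    mu = {c.name: c.friction for c in model.contacts}
    contact_active = {name: np.zeros(len(st), dtype=bool)
                      for name, st in contact_states.items()}

    # Outer fixed-point with adaptive under-relaxation: active sets (and the
    # friction state) are evaluated at u_eval, a relaxed blend of successive
    # solutions.  Near-mechanism intermediate states (all posterior trusses
    # slack before the facets engage) otherwise make the pure active-set
    # iteration oscillate or diverge.
    u_eval: np.ndarray | None = None
    u_node = None
    u_node_prev = None
    omega = 1.0
    du_prev = np.inf
    n_outer = 0
    converged = False
    friction_updates = 0
    last_kt: dict = {}
    for it in range(options.max_outer):
        n_outer = it + 1
        K_truss = assemble_trusses(model, truss_active)
        frozen = last_kt if friction_updates >= options.friction_passes else None
        Kc, fc, last_kt = _contact_system(model, contact_states, contact_active,
                                          u_eval, mu, kt_frozen=frozen)
        if u_eval is not None and frozen is None and last_kt:
            friction_updates += 1
        K_red = K_solid_red + reduce_delta(K_truss + Kc)
        if nfull > n_node_dof:
            f_node_ext = np.concatenate([fc, np.zeros(nfull - n_node_dof)])
        else:
            f_node_ext = fc
        f_red = red.C.T @ (f_full + f_node_ext)
        u_red = _factor_solve(K_red, f_red)
        u_full = red.C @ u_red
        u_node = u_full[:n_node_dof].reshape(-1, 3)
        K_red_last, f_red_last, u_red_last = K_red, f_red, u_red

        if u_eval is None:
            du = np.inf
            stalls = 0
            u_eval = u_node.copy()
        else:
            du = np.linalg.norm(u_node - u_eval)
            if np.isfinite(du_prev):
                if du > 1.2 * du_prev:
                    omega = max(0.1, 0.5 * omega)   # divergence guard
                    stalls = 0
                elif du > 0.95 * du_prev:
                    stalls += 1                     # 2-cycle / plateau guard
                    if stalls >= 4:
                        omega = max(0.1, 0.5 * omega)
                        stalls = 0
                else:
                    stalls = 0
                    omega = min(1.0, 1.25 * omega)
            u_eval = u_eval + omega * (u_node - u_eval)
        du_prev = du

        # re-evaluate active sets at the relaxed displacement (bilateral
        # bond trusses never deactivate)
        new_truss = truss_active.copy()
        t_only = model.tension_only
        for eid, conn in _truss_elements(model):
            if t_only is not None and not t_only[eid]:
                continue
            eps = truss_axial_strain(mesh.nodes[conn], u_eval[conn].ravel())
            new_truss[eid] = eps > -1e-14
        new_contact = {}
        for cname, states in contact_states.items():
            act = np.zeros(len(states), dtype=bool)
            for k, st in enumerate(states):
                g = st.gap0 + _contact_relative_disp(st, u_eval) @ st.normal
                act[k] = g < 0
            new_contact[cname] = act

        sets_same = bool(np.array_equal(new_truss, truss_active) and
                         all(np.array_equal(new_contact[c], contact_active[c])
                             for c in contact_active))
        if log.isEnabledFor(logging.DEBUG):
            log.debug("outer %d: trusses %d->%d, contact %s->%s, |u|max %.4g, "
                      "du %.3g, omega %.3f", it, int(truss_active.sum()),
                      int(new_truss.sum()),
                      {c: int(a.sum()) for c, a in contact_active.items()},
                      {c: int(a.sum()) for c, a in new_contact.items()},
                      float(np.abs(u_node).max()), du, omega)
        any_contact = (any(a.any() for a in new_contact.values()) or
                       any(a.any() for a in contact_active.values()))
        if u_node_prev is None:
            settled = False
        else:
            rel_du = (np.linalg.norm(u_node - u_node_prev) /
                      max(np.linalg.norm(u_node), 1e-30))
            settled = rel_du <= max(options.contact_rtol, options.rtol)
        u_node_prev = u_node.copy()
        truss_active, contact_active = new_truss, new_contact
        # Piecewise-linear fixed point: the solve used active sets S and the
        # relaxed state reproduces S.  Without engaged contact the solution
        # for fixed S is exact; with contact the friction state is history
        # dependent, so additionally require the relaxed state to settle.
        if sets_same and (not any_contact or settled):
            converged = True
            break
    if not converged:
        raise FemError(f"no convergence within max_outer={options.max_outer}")

    # penetration check
    slips: dict[str, np.ndarray] = {}
    for cname, states in contact_states.items():
        s = np.zeros(len(states))
        for k, st in enumerate(states):
            urel = _contact_relative_disp(st, u_node)
            g = st.gap0 + urel @ st.normal
            if g < -options.penetration_tol * 50:
                raise FemError(
                    f"contact {cname}: penetration {abs(g):.3e} mm at slave {st.slave}")
            s[k] = np.linalg.norm(urel - (urel @ st.normal) * st.normal)
        slips[cname] = s

    strain, truss_eps = compute_element_strain_arrays(model, u_node)
    # energy balance on the final linear system
    num = float(u_red_last @ (K_red_last @ u_red_last))
    den = float(f_red_last @ u_red_last)
    ratio = num / den if den != 0 else 1.0
    return SolveResult(u=u_node, strain=strain, truss_axial=truss_eps,
                       truss_active=truss_active, slips=slips,
                       contact_active=contact_active, n_outer=n_outer,
                       energy_ratio=ratio, f_ext=f_full)


def compute_element_strain_arrays(model: Model, u_node: np.ndarray):
    """Volume-averaged strain tensor per solid element + truss axial strain."""
    mesh = model.mesh
    strain = np.zeros((mesh.n_elems, 6))
    truss_eps = np.full(mesh.n_elems, np.nan)
    for eid, kind, conn in mesh.iter_elements():
        ue = u_node[conn].ravel()
        if kind == "truss2":
            truss_eps[eid] = truss_axial_strain(mesh.nodes[conn], ue)
        else:
            strain[eid] = element_strain_solid(mesh.nodes[conn], kind, ue)
    return strain, truss_eps


def compute_element_strain(result: SolveResult, model: Model) -> np.ndarray:
    """Recompute per-element strain tensors from a result's displacements."""
    strain, _ = compute_element_strain_arrays(model, result.u)
    return strain
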