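"""Assembly, constraints and the static solver against closed forms and a
dense brute-force oracle."""

import numpy as np
import pytest

from cervifem.elements import element_stiffness_solid, element_stiffness_truss
from cervifem.fem import (Coupling, FemError, Model, SolveOptions, assemble,
                          compute_element_strain_arrays, solve_static)
from cervifem.mesh import Mesh, box_mesh, tet4_to_tet10


def _bar_model(E=20.0, A=38.0, L=10.0):
    m = Mesh(np.array([[0.0, 0, 0], [L, 0, 0]]))
    m.add_block("truss2", np.array([[0, 1]]))
    m.node_sets["fix"] = np.array([0])
    return Model(mesh=m, E=np.array([E]), nu=np.array([0.3]), area=np.array([A]))


def test_bar_closed_form(point_case):
    """Axial bar: tip displacement F L / (E A)."""
    model = _bar_model()
    res = solve_static(model, point_case({1: [5.0, 0, 0]}, "fix"))
    assert res.u[1, 0] == pytest.approx(5.0 * 10 / (20 * 38), rel=1e-12)
    assert res.truss_axial[0] == pytest.approx(res.u[1, 0] / 10.0)


def test_truss_strain_definition(point_case):
    """Bar stretched by delta reports axial strain delta / L."""
    model = _bar_model(E=70.0, A=20.0, L=20.0)
    res = solve_static(model, point_case({1: [7.0, 0, 0]}, "fix"))
    assert res.truss_axial[0] == pytest.approx(res.u[1, 0] / 20.0, rel=1e-12)


def test_tension_only_member_carries_no_compression(point_case):
    """A 1-D two-member chain pushed sideways: the compressed member is
    deactivated and its final axial force is zero."""
    m = Mesh(np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]]))
    m.add_block("truss2", np.array([[0, 1], [1, 2]]))
    m.node_sets["fix"] = np.array([0, 2])
    model = Model(mesh=m, E=np.array([20.0, 20.0]), nu=np.full(2, 0.3),
                  area=np.array([38.0, 38.0]))
    res = solve_static(model, point_case({1: [5.0, 0, 0]}, "fix"))
    assert res.truss_active[0] and not res.truss_active[1]
    force_right = 20.0 * 38.0 * res.truss_axial[1] * res.truss_active[1]
    assert force_right >= -1e-9
    # all load now on the left member
    assert res.u[1, 0] == pytest.approx(5.0 * 10 / (20 * 38), rel=1e-9)


def test_tie_merges_displacements(point_case):
    """Two coincident tied nodes share their displacement in any solve."""
    m = Mesh(np.array([[0.0, 0, 0], [10.0, 0, 0], [10.0, 0, 0]]))
    m.add_block("truss2", np.array([[0, 1]]))
    m.node_sets["fix"] = np.array([0])
    model = Model(mesh=m, E=np.array([20.0]), nu=np.array([0.3]),
                  area=np.array([38.0]), ties=[(1, 2)])
    res = solve_static(model, point_case({2: [5.0, 0, 0]}, "fix"))
    assert np.allclose(res.u[1], res.u[2])
    assert res.u[1, 0] == pytest.approx(5.0 * 10 / (20 * 38), rel=1e-9)


def test_zero_load_zero_state(point_case):
    model = _bar_model()
    res = solve_static(model, point_case({}, "fix"))
    assert np.allclose(res.u, 0.0)
    assert np.allclose(res.strain, 0.0)


def test_assembled_stiffness_symmetric(two_level_model, torque_case):
    K, f, _red = assemble(two_level_model, torque_case([0.0, 0, 100.0]))
    asym = abs(K - K.T).max()
    assert asym <= 1e-8 * abs(K).max()


def test_cantilever_vs_beam_theory(point_case):
    """1x1x10 mm tet10 cantilever under a tip shear load lands within 8% of
    the Euler-Bernoulli deflection F L^3 / (3 E I)."""
    m = tet4_to_tet10(box_mesh(1.0, 1.0, 10.0, 2, 2, 10))
    ne = m.n_elems
    model = Model(mesh=m, E=np.full(ne, 1000.0), nu=np.zeros(ne), area=np.zeros(ne))
    tip = m.node_sets["top"]
    F = 1.0
    forces = {int(n): [F / len(tip), 0, 0] for n in tip}
    res = solve_static(model, point_case(forces, "bottom"))
    delta = res.u[tip, 0].mean()
    expected = F * 10.0**3 / (3.0 * 1000.0 * (1.0 / 12.0))
    assert delta == pytest.approx(expected, rel=0.08)
    assert res.energy_ratio == pytest.approx(1.0, abs=1e-6)


def test_energy_balance_on_bar(point_case):
    res = solve_static(_bar_model(), point_case({1: [5.0, 0, 0]}, "fix"))
    assert res.energy_ratio == pytest.approx(1.0, abs=1e-6)


def test_dense_oracle_equivalence(point_case, torque_case):
    """On a <=300-DOF fixture with a tie, a coupling and a truss, the sparse
    reduced solve matches an explicit dense elimination to 1e-8."""
    m = box_mesh(1.0, 1.0, 2.0, 1, 1, 2)           # 18 nodes
    mids = [int(n) for n in range(m.n_nodes)
            if abs(m.nodes[n, 2] - 1.0) < 1e-9]
    q = mids[0]
    m.nodes = np.vstack([m.nodes, m.nodes[q][None, :]])   # coincident twin
    dup = m.n_nodes - 1
    top_corner = int(m.node_sets["top"][0])
    bot_corner = int(m.node_sets["bottom"][0])
    m.add_block("truss2", np.array([[bot_corner, top_corner]]))
    ne = m.n_elems
    E = np.full(ne, 500.0)
    E[-1] = 20.0
    nu = np.full(ne, 0.3)
    area = np.zeros(ne)
    area[-1] = 38.0
    model = Model(mesh=m, E=E, nu=nu, area=area, ties=[(q, dup)])
    model.couplings["top"] = Coupling(ref_point=np.array([0.5, 0.5, 2.0]),
                                      node_set="top")
    tq = np.array([0.0, 50.0, 0.0])

    class Case:
        coupling = "top"
        fixed_set = "bottom"
        torque = tq

        def nodal_forces(self, model):
            return {dup: np.array([1.0, 0.0, 2.0])}

    res = solve_static(model, Case())
    assert np.allclose(res.u[q], res.u[dup])

    # --- independent dense path ---------------------------------------
    nn = m.n_nodes
    Kd = np.zeros((3 * nn, 3 * nn))
    for eid, kind, conn in m.iter_elements():
        if kind == "truss2":
            Ke = element_stiffness_truss(m.nodes[conn], E[eid], area[eid])
        else:
            Ke = element_stiffness_solid(m.nodes[conn], E[eid], nu[eid], kind)
        dofs = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in conn])
        Kd[np.ix_(dofs, dofs)] += Ke
    fixed = set(int(n) for n in m.node_sets["bottom"])
    followers = set(int(n) for n in m.node_sets["top"])
    free = [n for n in range(nn) if n not in fixed and n not in followers
            and n != dup]
    nred = 3 * len(free) + 6
    C = np.zeros((3 * nn, nred))
    for k, n in enumerate(free):
        C[3 * n:3 * n + 3, 3 * k:3 * k + 3] = np.eye(3)
    C[3 * dup:3 * dup + 3, :] = C[3 * q:3 * q + 3, :]     # tie: shared DOFs
    ref0 = 3 * len(free)
    ref_pt = np.array([0.5, 0.5, 2.0])
    for n in followers:
        r = m.nodes[n] - ref_pt
        C[3 * n:3 * n + 3, ref0:ref0 + 3] = np.eye(3)
        C[3 * n:3 * n + 3, ref0 + 3:ref0 + 6] = np.array(
            [[0, r[2], -r[1]], [-r[2], 0, r[0]], [r[1], -r[0], 0]])
    f_full = np.zeros(3 * nn)
    f_full[3 * dup:3 * dup + 3] = [1.0, 0.0, 2.0]
    f_red = C.T @ f_full
    f_red[ref0 + 3:ref0 + 6] += tq
    u_red = np.linalg.solve(C.T @ Kd @ C, f_red)
    u_dense = (C @ u_red).reshape(-1, 3)
    scale = np.abs(u_dense).max()
    assert np.abs(res.u - u_dense).max() <= 1e-8 * scale


def test_prescribed_linear_field_strain_exact():
    """u = (alpha x, 0, 0) reports eps_xx = alpha in every solid element."""
    m = tet4_to_tet10(box_mesh(2.0, 2.0, 2.0, 2, 2, 2))
    ne = m.n_elems
    model = Model(mesh=m, E=np.ones(ne), nu=np.zeros(ne), area=np.zeros(ne))
    alpha = 0.01
    u = np.zeros((m.n_nodes, 3))
    u[:, 0] = alpha * m.nodes[:, 0]
    strain, _ = compute_element_strain_arrays(model, u)
    assert np.allclose(strain[:, 0], alpha, atol=1e-12)
    assert np.abs(strain[:, 1:]).max() < 1e-12


def test_rigid_rotation_strain_second_order():
    m = box_mesh(2.0, 2.0, 2.0, 1, 1, 1)
    ne = m.n_elems
    model = Model(mesh=m, E=np.ones(ne), nu=np.zeros(ne), area=np.zeros(ne))
    theta = 1e-4
    c = m.nodes.mean(axis=0)
    u = np.cross([0, 0, theta], m.nodes - c)
    strain, _ = compute_element_strain_arrays(model, u)
    assert np.abs(strain).max() <= 10 * theta**2


def test_refinement_reduces_beam_error(point_case):
    """Energy-norm error against an over-refined reference decreases
    monotonically under tet4 refinement of the cantilever fixture."""
    def tip_deflection(nx, nz, quad=False):
        m = box_mesh(1.0, 1.0, 10.0, nx, nx, nz)
        if quad:
            m = tet4_to_tet10(m)
        ne = m.n_elems
        model = Model(mesh=m, E=np.full(ne, 1000.0), nu=np.zeros(ne),
                      area=np.zeros(ne))
        tip = m.node_sets["top"]
        forces = {int(n): [1.0 / len(tip), 0, 0] for n in tip}
        res = solve_static(model, point_case(forces, "bottom"))
        return res.u[tip, 0].mean()

    ref = tip_deflection(2, 10, quad=True)
    err = [abs(tip_deflection(1, 5) - ref), abs(tip_deflection(2, 10) - ref),
           abs(tip_deflection(3, 15) - ref)]
    assert err[0] > err[1] > err[2]


def test_global_moment_balance(two_level_model, torque_case):
    """The applied torque is reacted at the base: interpolated constraints
    and bonds must not absorb moment (leak below 2%)."""
    from cervifem.fem import assemble_trusses
    from cervifem.mesh import merge_pairs_map

    model = two_level_model
    tq = np.array([500.0, 0.0, 0.0])     # flexion opens the facets
    res = solve_static(model, torque_case(tq))
    assert all(a.sum() == 0 for a in res.contact_active.values())
    mesh = model.mesh
    K = model._cache["K_solid"] + assemble_trusses(model, res.truss_active)
    resid = (K @ res.u.ravel()).reshape(-1, 3)
    rep = merge_pairs_map(mesh.n_nodes, model.ties)
    fixed = set(int(rep[i]) for i in mesh.node_sets["base"])
    c = mesh.nodes[mesh.node_sets["base"]].mean(axis=0)
    bn = [i for i in range(mesh.n_nodes) if int(rep[i]) in fixed]
    M_base = np.sum(np.cross(mesh.nodes[bn] - c, resid[bn]), axis=0)
    spin = mesh.node_sets["spinous_C5"]
    M_applied = np.sum(np.cross(mesh.nodes[spin] - c, resid[spin]), axis=0)
    assert np.allclose(M_applied, tq, atol=0.01 * np.linalg.norm(tq))
    leak = np.linalg.norm(M_base + M_applied)
    assert leak <= 0.02 * np.linalg.norm(tq)


def test_floating_structure_raises(point_case):
    m = Mesh(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
    m.add_block("truss2", np.array([[0, 1]]))
    m.node_sets["fix"] = np.array([], dtype=np.int64)
    model = Model(mesh=m, E=np.array([20.0]), nu=np.array([0.3]),
                  area=np.array([38.0]))
    with pytest.raises(FemError):
        solve_static(model, point_case({1: [0, 5.0, 0]}, "fix"))
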