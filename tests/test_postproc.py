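"""Principal strains, damage index, segmental ROM, trajectory summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervifem.fem import SolveResult, solve_static
from cervifem.postproc import (DamageThresholds, PostprocError, Verdict,
                               damage_index, damage_report, principal_strains,
                               safety_verdict, segment_rom, trajectory_report,
                               _fit_rotation)


def _rotation(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    t = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * K @ K


# ----------------------------------------------------------------------
# principal strains


def test_isotropic_tensor():
    ps = principal_strains(np.diag([0.01, 0.01, 0.01]))
    assert ps.eps1 == ps.eps2 == ps.eps3 == pytest.approx(0.01)


def test_pure_shear_principals():
    """Engineering shear gamma -> principals (+gamma/2, 0, -gamma/2)."""
    g = 0.004
    ps = principal_strains(np.array([0.0, 0, 0, g, 0, 0]))  # 6-vector form
    assert ps.eps1 == pytest.approx(g / 2)
    assert ps.eps2 == pytest.approx(0.0, abs=1e-15)
    assert ps.eps3 == pytest.approx(-g / 2)


def test_extension_extremes_example():
    """The worked tension/compression pair 1.47% / -1.67%."""
    ps = principal_strains(np.diag([0.0147, 0.0, -0.0167]))
    assert ps.eps1 == pytest.approx(0.0147)
    assert ps.eps3 == pytest.approx(-0.0167)


def test_asymmetric_tensor_rejected():
    t = np.zeros((3, 3))
    t[0, 1] = 1e-3
    with pytest.raises(PostprocError):
        principal_strains(t)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-0.05, 0.05), min_size=6, max_size=6),
       st.floats(0.1, 3.0), st.integers(0, 2))
def test_principal_rotation_invariance(vec, angle, axis_idx):
    """Rotating the tensor leaves its principal values unchanged."""
    from cervifem.postproc import strain_tensor

    t = strain_tensor(np.array(vec))
    R = _rotation(np.eye(3)[axis_idx], np.degrees(angle))
    p0 = principal_strains(t)
    p1 = principal_strains(R @ t @ R.T)
    assert np.allclose([p0.eps1, p0.eps2, p0.eps3],
                       [p1.eps1, p1.eps2, p1.eps3], atol=1e-10)


# ----------------------------------------------------------------------
# damage index


def test_damage_worked_example():
    """eps1 = 1.47%, eps3 = -1.67% against limits (1.5%, -2.0%): the index is
    max(0.98, 0.835) = 0.98 -- below the failure threshold of one."""
    ps = principal_strains(np.diag([0.0147, 0.0, -0.0167]))
    di = damage_index(ps)
    assert di == pytest.approx(0.98, abs=1e-12)
    assert di < 1.0


@pytest.mark.parametrize("e1,e3,expected", [
    (0.015, 0.0, 1.0),         # tension boundary -> broken
    (0.0, -0.020, 1.0),        # compression boundary -> broken
    (0.0, 0.0, 0.0),
    (-0.004, -0.004, 0.2),     # pure compression: only eps3/eps_c counts
    (0.003, 0.001, 0.2),       # pure tension: only eps1/eps_t counts
])
def test_damage_boundaries_and_sign_rule(e1, e3, expected):
    from cervifem.postproc import PrincipalStrain

    ps = PrincipalStrain(e1, 0.5 * (e1 + e3), e3)
    assert damage_index(ps) == pytest.approx(expected)


def test_damage_threshold_monotonicity():
    """Tightening the limits can only raise the index (PASS can flip to FAIL,
    never the reverse)."""
    from cervifem.postproc import PrincipalStrain

    ps = PrincipalStrain(0.0147, 0.0, -0.0167)
    loose = damage_index(ps, DamageThresholds(0.015, -0.020))
    tight = damage_index(ps, DamageThresholds(0.005, -0.006))
    assert tight > loose
    assert tight > 1.0 > loose


def test_threshold_validation():
    with pytest.raises(PostprocError):
        DamageThresholds(-0.01, -0.02)


# ----------------------------------------------------------------------
# segmental ROM


def test_rom_recovers_imposed_rigid_rotation(two_level_model):
    """Imposing a rigid 5 deg rotation on the upper vertebra recovers 5.00."""
    model = two_level_model
    mesh = model.mesh
    u = np.zeros((mesh.n_nodes, 3))
    ids = mesh.node_sets["vert_C5"]
    c = mesh.nodes[ids].mean(axis=0)
    R = _rotation([1, 0, 0], 5.0)
    u[ids] = (mesh.nodes[ids] - c) @ R.T + c - mesh.nodes[ids]
    res = SolveResult(u=u, strain=np.zeros((mesh.n_elems, 6)),
                      truss_axial=np.full(mesh.n_elems, np.nan),
                      truss_active=np.zeros(mesh.n_elems, bool),
                      slips={}, contact_active={})
    rom = segment_rom(res, model, "C5-C6", axis=[1, 0, 0])
    assert rom == pytest.approx(5.0, abs=1e-6)
    assert segment_rom(res, model, "C5-C6") == pytest.approx(5.0, abs=1e-6)


def test_rom_zero_displacement(two_level_model):
    mesh = two_level_model.mesh
    res = SolveResult(u=np.zeros((mesh.n_nodes, 3)),
                      strain=np.zeros((mesh.n_elems, 6)),
                      truss_axial=np.full(mesh.n_elems, np.nan),
                      truss_active=np.zeros(mesh.n_elems, bool),
                      slips={}, contact_active={})
    assert segment_rom(res, two_level_model, "C5-C6") == 0.0


def test_rom_linearity_and_antisymmetry(torque_case):
    """Two stiff blocks joined by a soft interlayer (no contact, no trusses):
    negating the torque negates the angle; doubling it doubles the angle."""
    from cervifem.fem import Coupling, Model
    from cervifem.mesh import box_mesh

    m = box_mesh(10.0, 10.0, 24.0, 2, 2, 6)
    ne = m.n_elems
    cents = m.element_centroids()
    E = np.where((cents[:, 2] > 10.0) & (cents[:, 2] < 14.0), 3.0, 500.0)
    model = Model(mesh=m, E=E, nu=np.full(ne, 0.3), area=np.zeros(ne))
    model.couplings["top"] = Coupling(ref_point=np.array([5.0, 5.0, 24.0]),
                                      node_set="top")
    m.node_sets["vert_L"] = np.array([n for n in range(m.n_nodes)
                                      if m.nodes[n, 2] <= 10.0])
    m.node_sets["vert_U"] = np.array([n for n in range(m.n_nodes)
                                      if m.nodes[n, 2] >= 14.0])
    case = lambda mz: torque_case([0, 0, mz], coupling="top", fixed_set="bottom")
    r1 = solve_static(model, case(200.0))
    r2 = solve_static(model, case(-200.0))
    r3 = solve_static(model, case(400.0))
    # the displacement field itself is exactly linear in the load
    assert np.allclose(r3.u, 2 * r1.u, atol=1e-6 * np.abs(r1.u).max())
    assert np.allclose(r2.u, -r1.u, atol=1e-9 * np.abs(r1.u).max())
    a1 = segment_rom(r1, model, "U-L", axis=[0, 0, 1])
    a2 = segment_rom(r2, model, "U-L", axis=[0, 0, 1])
    a3 = segment_rom(r3, model, "U-L", axis=[0, 0, 1])
    assert a1 > 0.1
    assert a2 == pytest.approx(-a1, rel=1e-6)
    # the fitted angle picks up second-order finite-rotation terms ~theta^2
    assert a3 == pytest.approx(2 * a1, rel=5 * np.radians(a1) ** 2 + 1e-9)


def test_collinear_landmarks_rejected():
    x = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    with pytest.raises(PostprocError):
        _fit_rotation(x, np.zeros_like(x))


# ----------------------------------------------------------------------
# trajectory report & verdict


def test_trajectory_report_argmax_and_rows(instrumented_model):
    model = instrumented_model
    mesh = model.mesh
    strain = np.zeros((mesh.n_elems, 6))
    seeded = int(mesh.elem_sets["trajectory_C4_left"][3])
    strain[seeded, 0] = 0.02                       # seeded extreme element
    res = SolveResult(u=np.zeros((mesh.n_nodes, 3)), strain=strain,
                      truss_axial=np.full(mesh.n_elems, np.nan),
                      truss_active=np.zeros(mesh.n_elems, bool),
                      slips={}, contact_active={})
    table = trajectory_report(res, model)
    assert len(table) == 8
    row = table.loc["trajectory_C4_left"]
    assert row["worst_element"] == seeded
    assert row["max_eps1"] == pytest.approx(0.02)
    assert row["arc_position"] in ("anterior", "posterior")
    # all-zero strain -> all extremes zero
    res0 = SolveResult(u=np.zeros((mesh.n_nodes, 3)),
                       strain=np.zeros((mesh.n_elems, 6)),
                       truss_axial=np.full(mesh.n_elems, np.nan),
                       truss_active=np.zeros(mesh.n_elems, bool),
                       slips={}, contact_active={})
    t0 = trajectory_report(res0, model)
    assert (t0["max_di"] == 0).all()


def _report(motion, region_max):
    from cervifem.postproc import DamageReport

    return DamageReport(motion=motion, di=np.zeros(1),
                        thresholds=DamageThresholds(), region_max=region_max)


def test_verdict_pass_and_fail():
    motions = ("flexion", "extension", "lateral_flexion", "rotation")
    ok = {m: _report(m, {"central_body": 0.98}) for m in motions}
    v = safety_verdict(ok)
    assert v.passed and "PASS" in str(v)
    bad = dict(ok)
    bad["extension"] = _report("extension", {"central_body": 1.2})
    v2 = safety_verdict(bad)
    assert not v2.passed
    assert ("extension", "central_body", 1.2) in v2.offending
    with pytest.raises(PostprocError):
        safety_verdict({"flexion": ok["flexion"]})
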