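"""Element stiffness kernels: null spaces, patch consistency, trusses."""

import numpy as np
import pytest

from cervifem.elements import (ElementError, element_stiffness_solid,
                               element_stiffness_truss, element_strain_solid,
                               isotropic_D)
from cervifem.mesh import TET10_EDGES

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
TRI_EDGES = [(0, 1), (1, 2), (2, 0)]


def _tet10_coords(tet4):
    return np.vstack([tet4] + [0.5 * (tet4[i] + tet4[j]) for i, j in TET10_EDGES])


def _wedge15_coords(w6):
    return np.vstack([
        w6,
        [0.5 * (w6[i] + w6[j]) for i, j in TRI_EDGES],
        [0.5 * (w6[3 + i] + w6[3 + j]) for i, j in TRI_EDGES],
        [0.5 * (w6[i] + w6[3 + i]) for i in range(3)],
    ])


UNIT_WEDGE = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                       [0, 0, 1], [1, 0, 1], [0, 1, 1]])

ELEMENT_COORDS = {
    "tet4": UNIT_TET,
    "tet10": _tet10_coords(UNIT_TET),
    "wedge6": UNIT_WEDGE,
    "wedge15": _wedge15_coords(UNIT_WEDGE),
}


def test_tet4_matches_hand_assembled_b_matrix():
    """Constant-strain tet: K = V * B^T D B with B from the analytic shape
    gradients (independent construction)."""
    E, nu = 1000.0, 0.25
    x = np.array([[0.2, 0.1, 0.0], [1.1, 0.0, 0.2], [0.1, 1.3, 0.1], [0.3, 0.2, 1.2]])
    # gradients of the linear shape functions: rows of inverse coordinate matrix
    M = np.hstack([np.ones((4, 1)), x])
    Cinv = np.linalg.inv(M)          # shape i: N_i = Cinv[0,i] + Cinv[1:,i].x
    grads = Cinv[1:, :].T            # (4, 3)
    V = abs(np.linalg.det(M)) / 6.0
    B = np.zeros((6, 12))
    for i, g in enumerate(grads):
        B[0, 3 * i] = g[0]
        B[1, 3 * i + 1] = g[1]
        B[2, 3 * i + 2] = g[2]
        B[3, 3 * i] = g[1]
        B[3, 3 * i + 1] = g[0]
        B[4, 3 * i + 1] = g[2]
        B[4, 3 * i + 2] = g[1]
        B[5, 3 * i] = g[2]
        B[5, 3 * i + 2] = g[0]
    K_ref = V * B.T @ isotropic_D(E, nu) @ B
    K = element_stiffness_solid(x, E, nu, "tet4")
    assert np.allclose(K, K_ref, atol=1e-9 * np.abs(K_ref).max())


@pytest.mark.parametrize("kind", ["tet4", "tet10", "wedge6", "wedge15"])
def test_rigid_body_modes_in_null_space(kind):
    coords = ELEMENT_COORDS[kind]
    K = element_stiffness_solid(coords, 1000.0, 0.3, kind)
    nn = coords.shape[0]
    # translations
    for a in range(3):
        u = np.zeros((nn, 3))
        u[:, a] = 1.0
        assert np.abs(K @ u.ravel()).max() <= 1e-9 * np.abs(K).max()
    # infinitesimal rotations
    for axis in np.eye(3):
        u = np.cross(axis, coords - coords.mean(axis=0))
        assert np.abs(K @ u.ravel()).max() <= 1e-9 * np.abs(K).max()
    # exactly six near-zero eigenvalues (no spurious modes)
    w = np.linalg.eigvalsh(K)
    assert (w < 1e-8 * w.max()).sum() == 6


@pytest.mark.parametrize("kind", ["tet4", "tet10", "wedge6", "wedge15"])
def test_patch_consistency_linear_field(kind):
    """A linear displacement field must produce the exact constant strain."""
    coords = ELEMENT_COORDS[kind]
    A = np.array([[0.01, 0.002, 0.003], [0.004, 0.02, 0.001], [0.002, 0.005, 0.03]])
    u = (coords @ A.T).ravel()
    expected = np.array([A[0, 0], A[1, 1], A[2, 2],
                         A[0, 1] + A[1, 0], A[1, 2] + A[2, 1], A[0, 2] + A[2, 0]])
    eps = element_strain_solid(coords, kind, u)
    assert np.abs(eps - expected).max() < 1e-10


def test_tet10_quadratic_field_exact():
    """Quadratic fields are inside the tet10 basis: a bending-like field
    (u_x = -k z^2 / 2, u_z = k x z) carries zero shear and linear eps_zz."""
    coords = _tet10_coords(UNIT_TET)
    k = 0.01
    u = np.column_stack([-k * coords[:, 2] ** 2 / 2,
                         np.zeros(len(coords)),
                         k * coords[:, 0] * coords[:, 2]]).ravel()
    eps = element_strain_solid(coords, "tet10", u)
    assert eps[5] == pytest.approx(0.0, abs=1e-12)      # gamma_zx cancels
    assert eps[0] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("E,A,L,expected", [(20.0, 38.0, 10.0, 76.0),
                                            (70.0, 20.0, 20.0, 70.0)])
def test_truss_axial_stiffness(E, A, L, expected):
    K = element_stiffness_truss(np.array([[0.0, 0, 0], [L, 0, 0]]), E, A)
    assert K[0, 0] == pytest.approx(expected)
    assert K[0, 3] == pytest.approx(-expected)


def test_truss_frame_objectivity():
    """Rotating the element rotates its stiffness by the same rotation."""
    rng = np.random.default_rng(7)
    v = rng.normal(size=3)
    theta = 0.83
    k_axis = v / np.linalg.norm(v)
    K_mat = np.array([[0, -k_axis[2], k_axis[1]],
                      [k_axis[2], 0, -k_axis[0]],
                      [-k_axis[1], k_axis[0], 0]])
    R = (np.eye(3) + np.sin(theta) * K_mat + (1 - np.cos(theta)) * K_mat @ K_mat)
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    K0 = element_stiffness_truss(coords, 50.0, 10.0)
    K1 = element_stiffness_truss(coords @ R.T, 50.0, 10.0)
    T = np.kron(np.eye(2), R)
    assert np.allclose(K1, T @ K0 @ T.T, atol=1e-10)


def test_degenerate_elements_rejected():
    flat = UNIT_TET.copy()
    flat[3] = flat[0]                # zero volume
    with pytest.raises(ElementError):
        element_stiffness_solid(flat, 1000.0, 0.3, "tet4")
    with pytest.raises(ElementError):
        element_stiffness_truss(np.zeros((2, 3)), 20.0, 38.0)
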