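"""Isoparametric small-strain element kernels.

Engineering strain ordering (xx, yy, zz, xy, yz, zx) with engineering shear
components.  Units: mm, MPa, N.

Quadrature: tet4 1-point, tet10 4-point, wedge6 3x2 points, wedge15 7x3
points (the quadratic prism needs a degree-4-in-plane rule to keep full
rank of its 45-DOF stiffness).
"""

from __future__ import annotations

import numpy as np


class ElementError(ValueError):
    """Raised for degenerate element geometry (non-positive Jacobian)."""


# ----------------------------------------------------------------------
# quadrature rules in natural coordinates


def _tri_points_3() -> tuple[np.ndarray, np.ndarray]:
    pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
    w = np.full(3, 1 / 6)
    return pts, w


def _tri_points_7() -> tuple[np.ndarray, np.ndarray]:
    a, b = 0.059715871789770, 0.797426985353087
    pts = np.array([
        [1 / 3, 1 / 3],
        [a, (1 - a) / 2], [(1 - a) / 2, a], [(1 - a) / 2, (1 - a) / 2],
        [b, (1 - b) / 2], [(1 - b) / 2, b], [(1 - b) / 2, (1 - b) / 2],
    ])
    w = 0.5 * np.array([0.225,
                        0.132394152788506, 0.132394152788506, 0.132394152788506,
                        0.125939180544827, 0.125939180544827, 0.125939180544827])
    return pts, w


def quadrature(kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature points (nq, ndim_natural) and weights for an element kind."""
    if kind == "tet4":
        return np.array([[0.25, 0.25, 0.25]]), np.array([1 / 6])
    if kind == "tet10":
        a, b = 0.585410196624969, 0.138196601125011
        pts = np.array([[a, b, b], [b, a, b], [b, b, a], [b, b, b]])
        return pts, np.full(4, 1 / 24)
    if kind in ("wedge6", "wedge15"):
        if kind == "wedge6":
            tpts, tw = _tri_points_3()
            zpts = np.array([-1 / np.sqrt(3), 1 / np.sqrt(3)])
            zw = np.array([1.0, 1.0])
        else:
            tpts, tw = _tri_points_7()
            g = np.sqrt(3 / 5)
            zpts = np.array([-g, 0.0, g])
            zw = np.array([5 / 9, 8 / 9, 5 / 9])
        pts, ws = [], []
        for (xi, eta), wt in zip(tpts, tw):
            for z, wz in zip(zpts, zw):
                pts.append([xi, eta, z])
                ws.append(wt * wz)
        return np.array(pts), np.array(ws)
    raise ElementError(f"no quadrature for kind {kind!r}")


# ----------------------------------------------------------------------
# shape functions and natural derivatives


def shape_functions(kind: str, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return N (nq, nn) and dN/dnatural (nq, nn, 3) at the given points."""
    nq = pts.shape[0]
    if kind in ("tet4", "tet10"):
        xi, eta, zta = pts[:, 0], pts[:, 1], pts[:, 2]
        L = np.stack([1 - xi - eta - zta, xi, eta, zta], axis=1)  # (nq, 4)
        dL = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        if kind == "tet4":
            N = L
            dN = np.broadcast_to(dL, (nq, 4, 3)).copy()
            return N, dN
        edges = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
        N = np.empty((nq, 10))
        dN = np.empty((nq, 10, 3))
        for c in range(4):
            N[:, c] = L[:, c] * (2 * L[:, c] - 1)
            dN[:, c, :] = ((4 * L[:, c] - 1)[:, None]) * dL[c]
        for m, (i, j) in enumerate(edges):
            N[:, 4 + m] = 4 * L[:, i] * L[:, j]
            dN[:, 4 + m, :] = 4 * (L[:, i][:, None] * dL[j] + L[:, j][:, None] * dL[i])
        return N, dN
    if kind in ("wedge6", "wedge15"):
        xi, eta, z = pts[:, 0], pts[:, 1], pts[:, 2]
        L = np.stack([1 - xi - eta, xi, eta], axis=1)  # (nq, 3)
        dLdxi = np.array([[-1, -1], [1, 0], [0, 1]], dtype=float)  # dL/d(xi,eta)
        if kind == "wedge6":
            N = np.empty((nq, 6))
            dN = np.zeros((nq, 6, 3))
            for i in range(3):
                N[:, i] = 0.5 * L[:, i] * (1 - z)
                N[:, 3 + i] = 0.5 * L[:, i] * (1 + z)
                dN[:, i, :2] = 0.5 * (1 - z)[:, None] * dLdxi[i]
                dN[:, i, 2] = -0.5 * L[:, i]
                dN[:, 3 + i, :2] = 0.5 * (1 + z)[:, None] * dLdxi[i]
                dN[:, 3 + i, 2] = 0.5 * L[:, i]
            return N, dN
        # wedge15 (serendipity quadratic prism)
        N = np.empty((nq, 15))
        dN = np.zeros((nq, 15, 3))
        for i in range(3):
            Li = L[:, i]
            # bottom corner i
            N[:, i] = 0.5 * Li * ((2 * Li - 1) * (1 - z) - (1 - z**2))
            dN[:, i, :2] = (0.5 * ((4 * Li - 1) * (1 - z) - (1 - z**2)))[:, None] * dLdxi[i]
            dN[:, i, 2] = 0.5 * Li * (-(2 * Li - 1) + 2 * z)
            # top corner i
            N[:, 3 + i] = 0.5 * Li * ((2 * Li - 1) * (1 + z) - (1 - z**2))
            dN[:, 3 + i, :2] = (0.5 * ((4 * Li - 1) * (1 + z) - (1 - z**2)))[:, None] * dLdxi[i]
            dN[:, 3 + i, 2] = 0.5 * Li * ((2 * Li - 1) + 2 * z)
            # vertical mid-edge i
            N[:, 12 + i] = Li * (1 - z**2)
            dN[:, 12 + i, :2] = (1 - z**2)[:, None] * dLdxi[i]
            dN[:, 12 + i, 2] = -2 * z * Li
        tri_edges = [(0, 1), (1, 2), (2, 0)]
        for m, (i, j) in enumerate(tri_edges):
            Li, Lj = L[:, i], L[:, j]
            dLij = Li[:, None] * dLdxi[j] + Lj[:, None] * dLdxi[i]
            N[:, 6 + m] = 2 * Li * Lj * (1 - z)
            dN[:, 6 + m, :2] = 2 * (1 - z)[:, None] * dLij
            dN[:, 6 + m, 2] = -2 * Li * Lj
            N[:, 9 + m] = 2 * Li * Lj * (1 + z)
            dN[:, 9 + m, :2] = 2 * (1 + z)[:, None] * dLij
            dN[:, 9 + m, 2] = 2 * Li * Lj
        return N, dN
    raise ElementError(f"no shape functions for kind {kind!r}")


_SHAPE_CACHE: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _cached_shapes(kind: str):
    if kind not in _SHAPE_CACHE:
        pts, w = quadrature(kind)
        N, dN = shape_functions(kind, pts)
        _SHAPE_CACHE[kind] = (w, N, dN)
    return _SHAPE_CACHE[kind]


# ----------------------------------------------------------------------
# constitutive matrix


def isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (engineering shear)."""
    c = E / ((1 + nu) * (1 - 2 * nu))
    D = np.zeros((6, 6))
    D[:3, :3] = c * nu
    np.fill_diagonal(D[:3, :3], c * (1 - nu))
    g = c * (1 - 2 * nu) / 2
    D[3, 3] = D[4, 4] = D[5, 5] = g
    return D


def _b_matrices(kind: str, coords: np.ndarray):
    """Yield (B, detJ * weight) at each quadrature point."""
    w, _N, dN = _cached_shapes(kind)
    nn = coords.shape[0]
    for q in range(len(w)):
        J = dN[q].T @ coords          # J[a, b] = d x_b / d xi_a
        detJ = np.linalg.det(J)
        if detJ <= 0:
            raise ElementError(f"non-positive Jacobian ({detJ:.3e}) in {kind} element")
        dNdx = np.linalg.solve(J, dN[q].T).T  # dN/dx = dN @ inv(J)^T
        B = np.zeros((6, 3 * nn))
        B[0, 0::3] = dNdx[:, 0]
        B[1, 1::3] = dNdx[:, 1]
        B[2, 2::3] = dNdx[:, 2]
        B[3, 0::3] = dNdx[:, 1]
        B[3, 1::3] = dNdx[:, 0]
        B[4, 1::3] = dNdx[:, 2]
        B[4, 2::3] = dNdx[:, 1]
        B[5, 0::3] = dNdx[:, 2]
        B[5, 2::3] = dNdx[:, 0]
        yield B, detJ * w[q]


def element_stiffness_solid(coords: np.ndarray, E: float, nu: float, kind: str) -> np.ndarray:
    """Stiffness matrix (3n x 3n, N/mm) of a solid element.

    ``coords`` is (n_nodes, 3) in the element's node order.
    """
    nn = coords.shape[0]
    D = isotropic_D(E, nu)
    K = np.zeros((3 * nn, 3 * nn))
    for B, dv in _b_matrices(kind, coords):
        K += (B.T @ D @ B) * dv
    return 0.5 * (K + K.T)


def element_stiffness_truss(coords: np.ndarray, E: float, A: float) -> np.ndarray:
    """6x6 axial stiffness EA/L of a 2-node truss (no rotational DOFs)."""
    d = coords[1] - coords[0]
    L = np.linalg.norm(d)
    if L <= 0:
        raise ElementError("zero-length truss")
    d = d / L
    k = E * A / L
    dd = np.outer(d, d)
    K = np.zeros((6, 6))
    K[:3, :3] = K[3:, 3:] = k * dd
    K[:3, 3:] = K[3:, :3] = -k * dd
    return K


def element_strain_solid(coords: np.ndarray, kind: str, u_e: np.ndarray) -> np.ndarray:
    """Volume-averaged engineering strain 6-vector from element displacements."""
    acc = np.zeros(6)
    vol = 0.0
    for B, dv in _b_matrices(kind, coords):
        acc += (B @ u_e) * dv
        vol += dv
    return acc / vol


def truss_axial_strain(coords: np.ndarray, u_e: np.ndarray) -> float:
    """Axial strain of a truss: relative elongation along the element axis."""
    d = coords[1] - coords[0]
    L = np.linalg.norm(d)
    d = d / L
    return float(np.dot(u_e[3:] - u_e[:3], d) / L)
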