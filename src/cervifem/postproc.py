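"""Evaluation quantities: principal strains, damage indices, segmental
range of motion, per-trajectory strain summaries, and the safety verdict.

The damage index of a bone element is

    D_i = max(eps1_i / eps_t, eps3_i / eps_c)

where eps1/eps3 are the largest (tension) and smallest (compression)
principal strains and eps_t = +1.5%, eps_c = -2.0% are the strain limits.
A ratio counts only when the strain has the threshold's sign, so D_i >= 0,
and an element with D_i >= 1 is regarded as broken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class PostprocError(ValueError):
    """Raised for malformed tensors or missing sets/landmarks."""


# ----------------------------------------------------------------------
# principal strains


def strain_tensor(vec6: np.ndarray) -> np.ndarray:
    """3x3 tensor from engineering-ordered (xx, yy, zz, xy, yz, zx) vector."""
    xx, yy, zz, xy, yz, zx = vec6
    return np.array([[xx, xy / 2, zx / 2],
                     [xy / 2, yy, yz / 2],
                     [zx / 2, yz / 2, zz]])


@dataclass(frozen=True)
class PrincipalStrain:
    """Ordered principal strains eps1 >= eps2 >= eps3 of one element."""

    eps1: float
    eps2: float
    eps3: float
    element: int = -1

    def as_percent(self) -> tuple[float, float, float]:
        return 100 * self.eps1, 100 * self.eps2, 100 * self.eps3


def principal_strains(tensor: np.ndarray, element: int = -1,
                      atol: float = 1e-9) -> PrincipalStrain:
    """Eigenvalues of a symmetric strain tensor, sorted descending."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape == (6,):
        tensor = strain_tensor(tensor)
    if tensor.shape != (3, 3):
        raise PostprocError(f"expected 3x3 tensor or 6-vector, got {tensor.shape}")
    asym = np.max(np.abs(tensor - tensor.T))
    scale = max(np.max(np.abs(tensor)), 1.0)
    if asym > atol * scale:
        raise PostprocError(f"tensor asymmetric beyond tolerance ({asym:.2e})")
    w = np.linalg.eigvalsh(0.5 * (tensor + tensor.T))
    return PrincipalStrain(float(w[2]), float(w[1]), float(w[0]), element)


def principal_strain_fields(strain: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eps1, eps3) arrays over all elements from an (ne, 6) strain array."""
    ne = strain.shape[0]
    e1 = np.zeros(ne)
    e3 = np.zeros(ne)
    for i in range(ne):
        t = strain_tensor(strain[i])
        w = np.linalg.eigvalsh(t)
        e1[i], e3[i] = w[2], w[0]
    return e1, e3


def nodal_averaged_principals(model, strain: np.ndarray) -> np.ndarray:
    """Volume-weighted nodal average of the absolute-maximum principal
    strain (for surface maps; the element field drives the damage index)."""
    mesh = model.mesh
    e1, e3 = principal_strain_fields(strain)
    absmax = np.where(np.abs(e1) >= np.abs(e3), e1, e3)
    vols = mesh.element_volumes()
    acc = np.zeros(mesh.n_nodes)
    wsum = np.zeros(mesh.n_nodes)
    for eid, kind, conn in mesh.iter_elements():
        if kind == "truss2":
            continue
        acc[conn] += absmax[eid] * vols[eid]
        wsum[conn] += vols[eid]
    out = np.zeros(mesh.n_nodes)
    nz = wsum > 0
    out[nz] = acc[nz] / wsum[nz]
    return out


# ----------------------------------------------------------------------
# damage index


@dataclass(frozen=True)
class DamageThresholds:
    """Principal-strain limits: tension +1.5%, compression -2.0%."""

    tension_limit: float = 0.015
    compression_limit: float = -0.020

    def __post_init__(self) -> None:
        if not (self.tension_limit > 0 > self.compression_limit):
            raise PostprocError("need tension_limit > 0 > compression_limit")


def damage_index(ps: PrincipalStrain, th: DamageThresholds = DamageThresholds()) -> float:
    """D = max(eps1/eps_t, eps3/eps_c), each ratio floored at zero."""
    r_t = max(0.0, ps.eps1 / th.tension_limit)
    r_c = max(0.0, ps.eps3 / th.compression_limit)
    return max(r_t, r_c)


def damage_field(strain: np.ndarray, th: DamageThresholds = DamageThresholds()
                 ) -> np.ndarray:
    """Per-element damage indices from an (ne, 6) strain array."""
    e1, e3 = principal_strain_fields(strain)
    return np.maximum(np.maximum(0.0, e1 / th.tension_limit),
                      np.maximum(0.0, e3 / th.compression_limit))


@dataclass
class DamageReport:
    """Per-element damage indices with per-region maxima for one motion."""

    motion: str
    di: np.ndarray                      # (ne,)
    thresholds: DamageThresholds
    region_max: dict[str, float]

    @property
    def broken(self) -> np.ndarray:
        return self.di >= 1.0


def damage_report(model, result, motion: str,
                  th: DamageThresholds = DamageThresholds(),
                  regions: list[str] | None = None) -> DamageReport:
    """Damage indices over the bone element sets that matter for fixation:
    central bodies, screw trajectories, and spacer-contacting endplates."""
    di = damage_field(result.strain, th)
    if regions is None:
        regions = [n for n in model.mesh.elem_sets
                   if n == "central_body" or n.startswith("trajectory_")
                   or n.startswith("endplate_contact_")]
    region_max = {}
    for name in regions:
        ids = model.mesh.elem_sets[name]
        region_max[name] = float(di[ids].max()) if len(ids) else 0.0
    return DamageReport(motion=motion, di=di, thresholds=th, region_max=region_max)


# ----------------------------------------------------------------------
# segmental range of motion


def _fit_rotation(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Least-squares rigid rotation R mapping the undeformed landmark cloud
    onto the deformed one (Kabsch; translation removed first)."""
    if x.shape[0] < 3:
        raise PostprocError("need >= 3 landmark nodes for a rigid fit")
    y = x + u
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = np.linalg.matrix_rank(xc)
    if s < 2:
        raise PostprocError("landmark nodes are collinear; rotation fit is singular")
    H = xc.T @ yc
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R


def _rotation_vector(R: np.ndarray) -> np.ndarray:
    """Axis-angle vector of a rotation matrix (radians)."""
    cos = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos)
    if theta < 1e-12:
        return np.zeros(3)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return theta * w / (2.0 * np.sin(theta))


def vertebra_rotation(model, result, level: str) -> np.ndarray:
    """Best-fit rotation vector (radians) of one vertebra's node cloud."""
    name = f"vert_{level}"
    if name not in model.mesh.node_sets:
        raise PostprocError(f"model lacks node set {name!r}")
    ids = model.mesh.node_sets[name]
    return _rotation_vector(_fit_rotation(model.mesh.nodes[ids], result.u[ids]))


def segment_rom(result, model, junction: str,
                axis: np.ndarray | None = None) -> float:
    """Relative rotation (degrees) between the two vertebrae of a junction.

    The relative rotation R_rel = R_upper @ R_lower.T is projected on the
    motion ``axis`` (signed); without an axis the full rotation angle is
    returned.
    """
    up, lo = junction.split("-")
    for lv in (up, lo):
        if f"vert_{lv}" not in model.mesh.node_sets:
            raise PostprocError(f"junction {junction!r}: vertebra {lv} missing")
    ids_u = model.mesh.node_sets[f"vert_{up}"]
    ids_l = model.mesh.node_sets[f"vert_{lo}"]
    Ru = _fit_rotation(model.mesh.nodes[ids_u], result.u[ids_u])
    Rl = _fit_rotation(model.mesh.nodes[ids_l], result.u[ids_l])
    rv = _rotation_vector(Ru @ Rl.T)
    if axis is None:
        return float(np.degrees(np.linalg.norm(rv)))
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return float(np.degrees(rv @ axis))


def rom_table(model, results: dict[str, "object"],
              junctions: list[str] | None = None) -> pd.DataFrame:
    """Per-junction ROM (degrees, magnitude about each motion's axis) plus a
    combined flexion-extension column when both cases are present."""
    from .loading import MOTION_AXES

    if junctions is None:
        levels = model.meta["levels"]
        junctions = [f"{a}-{b}" for a, b in zip(levels[:-1], levels[1:])]
    rows = {}
    for j in junctions:
        row = {}
        for motion, res in results.items():
            ax = MOTION_AXES[motion]
            row[motion] = abs(segment_rom(res, model, j, axis=ax))
        if "flexion" in row and "extension" in row:
            row["flexion_extension"] = row["flexion"] + row["extension"]
        rows[j] = row
    return pd.DataFrame(rows).T.rename_axis("junction")


# ----------------------------------------------------------------------
# trajectory report


def trajectory_report(result, model) -> pd.DataFrame:
    """Per-screw-trajectory strain extremes and the location of the worst
    element along the shaft (anterior/posterior, medial/lateral)."""
    mesh = model.mesh
    names = sorted(n for n in mesh.elem_sets if n.startswith("trajectory_"))
    if not names:
        raise PostprocError("model has no trajectory element sets")
    e1, e3 = principal_strain_fields(result.strain)
    di = np.maximum(np.maximum(0.0, e1 / 0.015), np.maximum(0.0, e3 / -0.020))
    cents = mesh.element_centroids()
    axes = model.meta.get("screw_axes", {})
    rows = []
    for name in names:
        ids = mesh.elem_sets[name]
        if len(ids) == 0:
            raise PostprocError(f"trajectory set {name} is empty")
        worst = ids[int(np.argmax(di[ids]))]
        _, lv, side = name.split("_")
        row = {"trajectory": name, "level": lv, "side": side,
               "max_eps1": float(e1[ids].max()), "min_eps3": float(e3[ids].min()),
               "max_di": float(di[ids].max()), "worst_element": int(worst)}
        key = (lv, side)
        if key in axes:
            x_c, _z_c, y_s, y_t = axes[key]
            c = cents[worst]
            row["arc_position"] = "anterior" if c[1] < 0.5 * (y_s + y_t) else "posterior"
            lateral = (c[0] - x_c) * np.sign(x_c) > 0
            row["arc_side"] = "lateral" if lateral else "medial"
        rows.append(row)
    return pd.DataFrame(rows).set_index("trajectory")


# ----------------------------------------------------------------------
# verdict


@dataclass
class Verdict:
    passed: bool
    max_di: float
    offending: list[tuple[str, str, float]]   # (motion, region, max di)

    def __str__(self) -> str:
        if self.passed:
            return f"PASS (max damage index {self.max_di:.3f} < 1)"
        lines = [f"FAIL (max damage index {self.max_di:.3f})"]
        for motion, region, v in self.offending:
            lines.append(f"  {motion}: {region} max Di = {v:.3f}")
        return "\n".join(lines)


def safety_verdict(reports: dict[str, DamageReport],
                   required_motions: tuple[str, ...] = ("flexion", "extension",
                                                        "lateral_flexion", "rotation")
                   ) -> Verdict:
    """PASS iff every checked bone region stays below damage index 1 in all
    four motions; FAIL lists the offending motion/region pairs."""
    missing = [m for m in required_motions if m not in reports]
    if missing:
        raise PostprocError(f"missing damage reports for motions: {missing}")
    offending = []
    max_di = 0.0
    for motion in required_motions:
        rep = reports[motion]
        for region, v in rep.region_max.items():
            max_di = max(max_di, v)
            if v >= 1.0:
                offending.append((motion, region, v))
    return Verdict(passed=not offending, max_di=max_di, offending=offending)
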