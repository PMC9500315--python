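"""Motion load cases from body parameters and isometric neck strength.

The head weight (HW) is estimated as a fixed fraction of body weight
(default 7.83%) and applied as a vertical force split equally over the two
facet patches beside the C2 odontoid process.  Each of the four motions
(flexion, extension, lateral flexion, axial rotation) applies a torque
about its anatomical axis at a reference point kinematically coupled to the
C2 spinous-process node set; the torque equals the motion's isometric
strength (N*mm per kg body mass supported by the neck, i.e. per kg of head
mass) times the head mass.

Global axes of the phantom: x lateral, y anteroposterior (anterior = -y),
z vertical (superior = +z).  Flexion is a +x torque, extension -x, lateral
flexion +y, axial rotation +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MOTIONS = ("flexion", "extension", "lateral_flexion", "rotation")

#: torque axis (unit vector) and sign per motion
MOTION_AXES: dict[str, np.ndarray] = {
    "flexion": np.array([1.0, 0.0, 0.0]),
    "extension": np.array([-1.0, 0.0, 0.0]),
    "lateral_flexion": np.array([0.0, 1.0, 0.0]),
    "rotation": np.array([0.0, 0.0, 1.0]),
}


class LoadingError(ValueError):
    """Raised for invalid body parameters or missing model sets."""


@dataclass(frozen=True)
class BodyParams:
    """Patient body parameters driving the head-weight load."""

    body_mass: float                  # kg
    head_mass_fraction: float = 0.0783
    g: float = 9.81                   # m/s^2

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise LoadingError("body_mass must be > 0")
        if not (0.0 < self.head_mass_fraction < 1.0):
            raise LoadingError("head_mass_fraction must lie in (0, 1)")
        if self.g <= 0:
            raise LoadingError("g must be > 0")


@dataclass(frozen=True)
class IsometricStrengthTable:
    """Isometric cervical strength per motion, N*mm per kg of head mass."""

    flexion: float = 418.0
    extension: float = 683.0
    lateral_flexion: float = 542.0
    rotation: float = 208.0

    def __post_init__(self) -> None:
        for m in MOTIONS:
            if getattr(self, m) <= 0:
                raise LoadingError(f"strength for {m} must be > 0")

    def strength(self, motion: str) -> float:
        if motion not in MOTIONS:
            raise LoadingError(f"unknown motion {motion!r}")
        return float(getattr(self, motion))


@dataclass
class LoadCase:
    """One motion: gravity on the C2 facet patches + torque at the coupled
    reference point + base fixation."""

    motion: str
    gravity_force: float              # N, magnitude of the vertical head load
    torque: np.ndarray                # N*mm vector about the motion axis
    facet_sets: tuple[str, str] = ("c2_facet_left", "c2_facet_right")
    coupling: str = "c2_spinous"      # name of the kinematic coupling
    fixed_set: str = "base"

    def nodal_forces(self, model) -> dict[int, np.ndarray]:
        """Equal per-node split of the head weight over both facet patches."""
        forces: dict[int, np.ndarray] = {}
        per_side = 0.5 * self.gravity_force
        for sname in self.facet_sets:
            if sname not in model.mesh.node_sets:
                raise LoadingError(f"model is missing node set {sname!r}")
            ids = model.mesh.node_sets[sname]
            if len(ids) == 0:
                raise LoadingError(f"node set {sname!r} is empty")
            fz = -per_side / len(ids)
            for nid in ids:
                forces[int(nid)] = forces.get(int(nid), np.zeros(3)) + np.array([0.0, 0.0, fz])
        return forces


def head_weight_force(body: BodyParams) -> float:
    """Head weight in N: body_mass * head_mass_fraction * g."""
    return body.body_mass * body.head_mass_fraction * body.g


def motion_torque(strength: float, head_mass: float) -> int:
    """Torque in N*mm (rounded to integer for reporting).

    Parameters
    ----------
    strength : float
        Isometric strength for the motion, N*mm/kg.
    head_mass : float
        Supported head mass in kg (head weight / g).
    """
    if strength < 0 or head_mass < 0:
        raise LoadingError("strength and head_mass must be >= 0")
    return int(round(strength * head_mass))


def torque_table(body: BodyParams, table: IsometricStrengthTable) -> dict[str, int]:
    """All four motion torques (N*mm) for a body."""
    hm = head_weight_force(body) / body.g
    return {m: motion_torque(table.strength(m), hm) for m in MOTIONS}


def build_load_case(model, motion: str, body: BodyParams,
                    table: IsometricStrengthTable,
                    fix_level: str | None = None) -> LoadCase:
    """Construct the LoadCase for one motion on an assembled model.

    The torque vector is strength * head_mass along the motion axis; the
    gravity force is the head weight.  ``fix_level`` overrides the base
    fixation set with ``base_<level>`` (e.g. ``T1``) when the model provides
    it.
    """
    if motion not in MOTIONS:
        raise LoadingError(f"unknown motion {motion!r}")
    hw = head_weight_force(body)
    hm = hw / body.g
    tq = table.strength(motion) * hm
    fixed = "base"
    if fix_level is not None:
        fixed = f"base_{fix_level}"
    for sname in ("c2_facet_left", "c2_facet_right", fixed):
        if sname not in model.mesh.node_sets:
            raise LoadingError(f"model is missing node set {sname!r}")
    if "c2_spinous" not in model.couplings:
        raise LoadingError("model is missing the c2_spinous kinematic coupling")
    return LoadCase(motion=motion, gravity_force=hw,
                    torque=tq * MOTION_AXES[motion], fixed_set=fixed)
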