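"""Bone-density driven material model.

Trabecular bone regions carry a per-region volumetric bone mineral density
(BMD, mg/cc) measured separately in the central and exterior vertebral body.
BMD maps to a Young's modulus (MPa) through a power-law calibration.  Two
modes of the law are provided:

``as_used`` (default)
    E = 10200 * (BMD/1000)**2.01 for BMD > 0, E = 0.001 MPa at BMD = 0.
    This single power branch reproduces every tabulated trabecular modulus
    in the reference material card to the printed 0.01 MPa.

``as_printed``
    The four-branch piecewise calibration with branch thresholds 0.27 and
    0.60 g/cc applied to BMD/1000:

    ======================  =============================
    BMD/1000 (g/cc)          E (MPa)
    ======================  =============================
    0                        0.001
    (0, 0.27)                33900 * (BMD/1000)**2.2
    [0.27, 0.60]             5407 * (BMD/1000) + 469
    (0.60, inf)              10200 * (BMD/1000)**2.01
    ======================  =============================

All other constituents (cortical bone, nucleus pulposus, anulus fibrosus,
PEEK spacers, titanium hardware, the six ligament groups) use fixed
literature cards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class MaterialError(ValueError):
    """Raised for invalid material input (negative BMD, missing regions)."""


class LawMode(str, Enum):
    as_used = "as_used"
    as_printed = "as_printed"


@dataclass(frozen=True)
class DensityModulusLaw:
    """BMD (mg/cc) -> Young's modulus (MPa) mapping with a mode selector."""

    mode: LawMode = LawMode.as_used

    def __call__(self, bmd: float) -> float:
        return bmd_to_modulus(bmd, self)


@dataclass(frozen=True)
class MaterialCard:
    name: str
    youngs_modulus: float  # MPa
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise MaterialError(f"{self.name}: E must be > 0 (got {self.youngs_modulus})")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise MaterialError(f"{self.name}: nu must lie in (0, 0.5)")


@dataclass(frozen=True)
class RegionBmd:
    """Per-region density input: one vertebra level, one trabecular region."""

    level: str            # e.g. "C4"
    region: str           # "central_body" | "exterior_body"
    bmd: float            # mg/cc

    def __post_init__(self) -> None:
        if self.region not in ("central_body", "exterior_body"):
            raise MaterialError(f"unknown region {self.region!r}")
        if self.bmd < 0:
            raise MaterialError("bmd must be >= 0")


def bmd_to_modulus(bmd: float, law: DensityModulusLaw | LawMode | str = LawMode.as_used) -> float:
    """Map BMD in mg/cc to Young's modulus in MPa.

    Parameters
    ----------
    bmd : float
        Volumetric bone mineral density, mg/cc.  Must be >= 0.
    law : DensityModulusLaw or mode name
        ``as_used`` single power branch (default) or ``as_printed`` piecewise.
    """
    if isinstance(law, DensityModulusLaw):
        mode = law.mode
    else:
        mode = LawMode(law)
    if bmd < 0:
        raise MaterialError(f"bmd must be >= 0, got {bmd}")
    if bmd == 0:
        return 0.001
    rho = bmd / 1000.0  # g/cc
    if mode is LawMode.as_used:
        E = 10200.0 * rho**2.01
    elif rho < 0.27:
        E = 33900.0 * rho**2.2
    elif rho <= 0.60:
        E = 5407.0 * rho + 469.0
    else:
        E = 10200.0 * rho**2.01
    # the zero-density value 0.001 MPa acts as a numerical floor, keeping the
    # mapping monotone for vanishing densities
    return max(E, 0.001)


# ----------------------------------------------------------------------
# fixed constituent cards

CONSTANT_CARDS: dict[str, MaterialCard] = {
    "cortical": MaterialCard("cortical", 1000.0, 0.30),
    "NP": MaterialCard("NP", 1.0, 0.49),
    "AF": MaterialCard("AF", 3.4, 0.40),
    "PEEK": MaterialCard("PEEK", 4000.0, 0.35),
    "titanium": MaterialCard("titanium", 110000.0, 0.30),
}

#: ligament group -> (E MPa, nu, cross-section area mm^2)
LIGAMENT_CARDS: dict[str, tuple[float, float, float]] = {
    "ALL": (20.0, 0.3, 38.0),
    "PLL": (70.0, 0.3, 20.0),
    "ISL": (28.0, 0.3, 35.5),
    "SSL": (28.0, 0.3, 35.5),
    "ITL": (50.0, 0.3, 10.0),
    "LF": (50.0, 0.3, 60.0),
}

#: shipped per-region BMD input (mg/cc) for the worked example; the pipeline
#: accepts any per-patient list in the same shape.
EXAMPLE_REGION_BMD: list[RegionBmd] = [
    RegionBmd("C2", "central_body", 200.4), RegionBmd("C2", "exterior_body", 135.2),
    RegionBmd("C3", "central_body", 242.1), RegionBmd("C3", "exterior_body", 99.7),
    RegionBmd("C4", "central_body", 319.2), RegionBmd("C4", "exterior_body", 185.9),
    RegionBmd("C5", "central_body", 301.3), RegionBmd("C5", "exterior_body", 251.5),
    RegionBmd("C6", "central_body", 262.6), RegionBmd("C6", "exterior_body", 141.8),
    RegionBmd("C7", "central_body", 229.1), RegionBmd("C7", "exterior_body", 124.7),
    RegionBmd("T1", "central_body", 165.7), RegionBmd("T1", "exterior_body", 55.1),
    RegionBmd("T2", "central_body", 187.4), RegionBmd("T2", "exterior_body", 140.4),
]


def region_bmd_from_rows(rows) -> list[RegionBmd]:
    """Build a RegionBmd list from (region_name, bmd) rows where region_name
    is '<level>/<region>' (e.g. 'C4/central_body'), or from dicts with keys
    level, region, bmd."""
    out = []
    for row in rows:
        if isinstance(row, dict):
            out.append(RegionBmd(row["level"], row["region"], float(row["bmd"])))
        else:
            name, bmd = row
            level, region = name.split("/")
            out.append(RegionBmd(level, region, float(bmd)))
    return out


def assign_materials(model, bmd_list: list[RegionBmd],
                     law: DensityModulusLaw | None = None,
                     constants: dict[str, MaterialCard] | None = None):
    """Assign E/nu (and truss areas already set at generation) to a model.

    Every trabecular element set named ``central_body_<level>`` or
    ``exterior_body_<level>`` must have a matching :class:`RegionBmd` entry;
    posterior bony elements (``posterior_<level>``) take the level's exterior
    modulus.  Constituent sets (cortical, NP, AF, spacers, plate, screws,
    ligament groups) take their fixed cards.

    Returns the model with per-element ``E`` and ``nu`` arrays filled.
    """
    law = law or DensityModulusLaw()
    cards = dict(CONSTANT_CARDS)
    if constants:
        cards.update(constants)

    mesh = model.mesh
    ne = mesh.n_elems
    E = np.full(ne, -1.0)
    nu = np.full(ne, -1.0)

    by_key = {(r.level, r.region): r.bmd for r in bmd_list}
    missing: list[str] = []
    for name, eids in mesh.elem_sets.items():
        if name.startswith("central_body_") or name.startswith("exterior_body_"):
            region, level = name.rsplit("_", 1)
            if (level, region) not in by_key:
                missing.append(f"{level}/{region}")
                continue
            E[eids] = bmd_to_modulus(by_key[(level, region)], law)
            nu[eids] = 0.30
    if missing:
        raise MaterialError(
            "missing RegionBmd entries for regions: " + ", ".join(sorted(missing)))
    if not bmd_list and any(n.startswith(("central_body_", "exterior_body_"))
                            for n in mesh.elem_sets):
        raise MaterialError("empty bmd list for a model with trabecular sets")

    for name, eids in mesh.elem_sets.items():
        if name.startswith("posterior_"):
            # posterior elements (pedicles, laminae, processes) are
            # predominantly compact bone
            E[eids] = cards["cortical"].youngs_modulus
            nu[eids] = cards["cortical"].poisson_ratio
        elif name.startswith("cortical_"):
            E[eids], nu[eids] = cards["cortical"].youngs_modulus, cards["cortical"].poisson_ratio
        elif name.startswith("NP_"):
            E[eids], nu[eids] = cards["NP"].youngs_modulus, cards["NP"].poisson_ratio
        elif name.startswith("AF_"):
            E[eids], nu[eids] = cards["AF"].youngs_modulus, cards["AF"].poisson_ratio
        elif name.startswith("spacer_"):
            E[eids], nu[eids] = cards["PEEK"].youngs_modulus, cards["PEEK"].poisson_ratio
        elif name == "plate" or name.startswith("screw_") or name == "bond_screw":
            E[eids], nu[eids] = cards["titanium"].youngs_modulus, cards["titanium"].poisson_ratio
        elif name.startswith("lig_"):
            group = name.split("_")[1]
            if group not in LIGAMENT_CARDS:
                raise MaterialError(f"unknown ligament group {group!r} in set {name}")
            lE, lnu, _ = LIGAMENT_CARDS[group]
            E[eids], nu[eids] = lE, lnu

    unset = np.flatnonzero(E < 0)
    if len(unset):
        raise MaterialError(f"{len(unset)} elements not covered by any material set "
                            f"(first ids: {unset[:5].tolist()})")
    model.E = E
    model.nu = nu
    return model
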