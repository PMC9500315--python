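"""Run configuration: schema-validated YAML in fixed mm / N / MPa / N*mm units.

Unknown keys are rejected up front (validation-first contract): a config
either starts the pipeline or fails before any mesh work.  Field names spell
out their units; values in other units are rejected rather than converted.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .loading import MOTIONS, BodyParams, IsometricStrengthTable
from .materials import DensityModulusLaw, LawMode, RegionBmd
from .phantom import InstrumentSpec, PhantomSpec


class ConfigError(ValueError):
    """Schema violation in the run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    levels: tuple[str, ...] | None = None   # default: full C2..T2 stack
    mesh_size_mm: float = 3.0
    disc_height_mm: float = 5.0
    np_area_fraction: float = 0.43
    np_volume_fraction: float = 0.45
    cortical_thickness_cervical_mm: float = 0.28
    cortical_thickness_thoracic_mm: float = 0.24
    facet_gap_mm: float = 0.3
    quadratic: bool = True
    jitter: float = 0.0

    def to_spec(self, seed: int) -> PhantomSpec:
        kw = {}
        if self.levels is not None:
            kw["levels"] = tuple(self.levels)
        return PhantomSpec(
            **kw,
            mesh_size=self.mesh_size_mm, disc_height=self.disc_height_mm,
            np_area_fraction=self.np_area_fraction,
            np_volume_fraction=self.np_volume_fraction,
            cortical_thickness_cervical=self.cortical_thickness_cervical_mm,
            cortical_thickness_thoracic=self.cortical_thickness_thoracic_mm,
            facet_gap=self.facet_gap_mm, quadratic=self.quadratic,
            jitter=self.jitter, seed=seed)


class InstrumentSection(_Strict):
    spacer_heights_mm: tuple[float, ...] = (8.0, 8.0, 7.0)
    screw_diameter_mm: float = 4.0
    screw_length_mm: float = 15.0
    plate_length_mm: float = 55.0
    plate_width_mm: float = 16.0
    plate_thickness_mm: float = 2.25
    plate_span: tuple[str, ...] = ("C2", "C3", "C4", "C5")
    plate_standoff_mm: float = 0.0

    def to_spec(self) -> InstrumentSpec:
        return InstrumentSpec(
            spacer_heights=self.spacer_heights_mm,
            screw_diameter=self.screw_diameter_mm,
            screw_length=self.screw_length_mm,
            plate_length=self.plate_length_mm, plate_width=self.plate_width_mm,
            plate_thickness=self.plate_thickness_mm, plate_span=self.plate_span,
            plate_standoff=self.plate_standoff_mm)


class BmdRow(_Strict):
    level: str
    region: str
    bmd_mg_cc: float

    def to_region(self) -> RegionBmd:
        return RegionBmd(self.level, self.region, self.bmd_mg_cc)


class LoadSection(_Strict):
    body_mass_kg: float = 39.97
    head_fraction: float = 0.0783
    g_m_s2: float = 9.81
    strengths_nmm_per_kg: dict[str, float] = Field(
        default_factory=lambda: {"flexion": 418.0, "extension": 683.0,
                                 "lateral_flexion": 542.0, "rotation": 208.0})
    fix_level: str | None = None

    @field_validator("strengths_nmm_per_kg")
    @classmethod
    def _check_motions(cls, v):
        unknown = set(v) - set(MOTIONS)
        if unknown:
            raise ValueError(f"unknown motions {sorted(unknown)}")
        return v

    def body(self) -> BodyParams:
        return BodyParams(body_mass=self.body_mass_kg,
                          head_mass_fraction=self.head_fraction, g=self.g_m_s2)

    def strengths(self) -> IsometricStrengthTable:
        return IsometricStrengthTable(**self.strengths_nmm_per_kg)


class SolverSection(_Strict):
    rtol: float = 1e-8
    max_outer: int = 50


class OutputSection(_Strict):
    dir: str = "results_run"
    write_vtu: bool = False


class RunConfig(_Strict):
    """Top-level, schema-validated run configuration."""

    seed: int = 0
    log_level: str = "INFO"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    instrument: InstrumentSection | None = Field(default_factory=InstrumentSection)
    bmd: list[BmdRow] = Field(default_factory=list)
    law_mode: str = "as_used"
    load: LoadSection = Field(default_factory=LoadSection)
    solver: SolverSection = Field(default_factory=SolverSection)
    output: OutputSection = Field(default_factory=OutputSection)

    @field_validator("law_mode")
    @classmethod
    def _check_mode(cls, v):
        LawMode(v)
        return v

    def law(self) -> DensityModulusLaw:
        return DensityModulusLaw(LawMode(self.law_mode))

    def region_bmd(self) -> list[RegionBmd]:
        if not self.bmd:
            raise ConfigError("config must list per-region bmd entries")
        return [r.to_region() for r in self.bmd]

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path) -> RunConfig:
    """Parse + validate a YAML run config; any violation raises before any
    mesh or solve work happens."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
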