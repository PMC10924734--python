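"""Validated run configuration: YAML schema, defaults, hashing.

A :class:`RunConfig` is the single document that fully determines a run:
physical constants, ion species, morphology, protocol phases and solver
settings.  Unknown keys are rejected; units follow the field names
(``*_mM``, ``*_nm``, ``*_pA``, ``*_ms``, ``*_mV`` — converted to SI when the
domain objects are built).  Identical configs hash identically, and the hash
is stamped into every output so analyses can refuse mismatched inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .physics import IonSpecies, PhysicalConstants
from .protocols import MorphologySpec, Phase, Protocol
from .solver import SolverSettings

SCHEMA_VERSION = 1

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstantsConfig(_Strict):
    T_K: float = Field(310.0, gt=0)
    c_m_F_per_m2: float = Field(0.01, gt=0)

    def build(self) -> PhysicalConstants:
        return PhysicalConstants(T=self.T_K, c_m=self.c_m_F_per_m2)


class SpeciesConfig(_Strict):
    name: str
    z: int
    D_m2_per_s: float = Field(gt=0)
    n_rest_mM: float = Field(ge=0)

    def build(self) -> IonSpecies:
        return IonSpecies(self.name, self.z, self.D_m2_per_s, self.n_rest_mM)


def _default_species_cfg() -> list[SpeciesConfig]:
    return [
        SpeciesConfig(name="Na", z=1, D_m2_per_s=0.65e-9, n_rest_mM=10.0),
        SpeciesConfig(name="K", z=1, D_m2_per_s=1.0e-9, n_rest_mM=140.0),
        SpeciesConfig(name="Cl", z=-1, D_m2_per_s=1.0e-9, n_rest_mM=10.0),
    ]


class MorphologyConfig(_Strict):
    head_radius_nm: float | None = Field(250.0, gt=0)
    head_volume_um3: float | None = None
    neck_radius_nm: float = Field(35.0, gt=0)
    dend_radius_nm: float = Field(250.0, gt=0)
    n_head: int = Field(5, ge=1)
    n_neck: int = Field(5, ge=1)
    n_dend: int = Field(4, ge=1)
    h_nm: float = Field(100.0, gt=0)

    @model_validator(mode="after")
    def _one_head_spec(self):
        if self.head_volume_um3 is not None:
            object.__setattr__(self, "head_radius_nm", None)
        return self

    def build(self) -> MorphologySpec:
        return MorphologySpec(
            neck_radius=self.neck_radius_nm * 1e-9,
            head_radius=None if self.head_radius_nm is None else self.head_radius_nm * 1e-9,
            head_volume=None if self.head_volume_um3 is None else self.head_volume_um3 * 1e-18,
            dend_radius=self.dend_radius_nm * 1e-9,
            n_head=self.n_head,
            n_neck=self.n_neck,
            n_dend=self.n_dend,
            h=self.h_nm * 1e-9,
        )


class PhaseConfig(_Strict):
    duration_ms: float = Field(gt=0)
    i_in_pA: float = 0.0
    clamp_offset_mV: float | None = None

    def build(self) -> Phase:
        return Phase(
            self.duration_ms * 1e-3,
            self.i_in_pA * 1e-12,
            None if self.clamp_offset_mV is None else self.clamp_offset_mV * 1e-3,
        )


class SolverConfig(_Strict):
    dt_ns: float = Field(0.5, gt=0)
    record_stride: int = Field(2000, ge=1)
    guard_phi_V: float = Field(1.0, gt=0)

    def build(self) -> SolverSettings:
        return SolverSettings(
            dt=self.dt_ns * 1e-9,
            record_stride=self.record_stride,
            guard_phi=self.guard_phi_V,
        )


class RunConfig(_Strict):
    """Top-level, schema-versioned run description."""

    schema_version: int = SCHEMA_VERSION
    label: str = "run"
    phi_rest_mV: float = -70.0
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    species: list[SpeciesConfig] = Field(default_factory=_default_species_cfg)
    morphology: MorphologyConfig = Field(default_factory=MorphologyConfig)
    protocol: list[PhaseConfig] = Field(
        default_factory=lambda: [
            PhaseConfig(duration_ms=10.0, i_in_pA=25.0),
            PhaseConfig(duration_ms=40.0),
        ]
    )
    solver: SolverConfig = Field(default_factory=SolverConfig)

    @model_validator(mode="after")
    def _check(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        if not self.species:
            raise ValueError("at least one species required")
        if not self.protocol:
            raise ValueError("protocol needs at least one phase")
        return self

    def build(self):
        """Materialize (geometry, species, protocol, settings, constants, phi_rest)."""
        morph = self.morphology.build()
        return (
            morph.to_geometry(),
            tuple(s.build() for s in self.species),
            Protocol(tuple(p.build() for p in self.protocol), label=self.label),
            self.solver.build(),
            self.constants.build(),
            self.phi_rest_mV * 1e-3,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; omitted fields take the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    canon = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
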