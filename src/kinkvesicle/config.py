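"""Run configuration: validated, serializable, provenance-complete.

A :class:`RunConfig` collects every knob of a simulation campaign
(physical constants, membrane and rod specs, rod density, protocol script,
replica count and seed base, analysis thresholds). Unknown keys are
rejected; every defaulted value is echoed back on serialization so a run's
sidecar alone reproduces it.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .analysis import ClassifierThresholds
from .dynamics import ActivationEvent, KinkRampEvent, Protocol
from .errors import ConfigError
from .params import RodSpec, SimulationParams, VesicleSpec

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsConfig(_Base):
    box_length: float = 125.0
    timestep: float = 1.0e-4
    temperature: float = 0.01
    gamma_t: float = 1.0
    gamma_r: float | None = None
    epsilon_wca: float = 10.0
    duration: float = 2.0e4

    def build(self, seed: int = 0) -> SimulationParams:
        return SimulationParams(seed=seed, **self.model_dump())


class VesicleConfig(_Base):
    n_disks: int = 100
    disk_diameter: float = 1.0
    bond_strength: float = 1.0
    fene_r0: float = 2.0
    bend_coeff: float = 10.0
    kink_index: int = 0
    kink_angle: float = math.pi
    kink_stiffness_multiplier: float = 10.0
    rigid_kink: bool = False

    def build(self) -> VesicleSpec:
        return VesicleSpec(**self.model_dump())


class RodConfig(_Base):
    n_disks: int = 3
    peclet: float = 75.0
    species: str = "A"
    active: bool = True
    #: share of the rods belonging to this species (fractions must sum to 1)
    fraction: float = 1.0

    def build(self) -> RodSpec:
        return RodSpec(n_disks=self.n_disks, peclet=self.peclet,
                       species=self.species, active=self.active)


class EventConfig(_Base):
    type: Literal["activate", "deactivate", "ramp_kink"]
    time: float
    species: str | None = None
    time_end: float | None = None
    theta_start: float | None = None
    theta_end: float | None = None

    def build(self):
        if self.type in ("activate", "deactivate"):
            if self.species is None:
                raise ConfigError("activation event needs a species")
            return ActivationEvent(self.time, self.species,
                                   self.type == "activate")
        if None in (self.time_end, self.theta_start, self.theta_end):
            raise ConfigError("ramp_kink needs time_end/theta_start/theta_end")
        return KinkRampEvent(self.time, self.time_end,
                             self.theta_start, self.theta_end)


class ThresholdsConfig(_Base):
    cluster_cutoff: float = 1.2
    min_cluster_fraction: float = 0.5
    min_frame_fraction: float = 0.5
    linear_radius: float = 500.0
    window: float = 0.5
    cluster_stride: int = 1

    def build(self) -> ClassifierThresholds:
        return ClassifierThresholds(**self.model_dump())


class RunConfig(_Base):
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    vesicle: VesicleConfig = Field(default_factory=VesicleConfig)
    rods: list[RodConfig] = Field(default_factory=lambda: [RodConfig()])
    density: float = 0.1
    replicas: int = 1
    seed_base: int = 0
    output_stride: int = 10_000
    thresholds: ThresholdsConfig = Field(default_factory=ThresholdsConfig)
    protocol: list[EventConfig] = Field(default_factory=list)

    @field_validator("rods")
    @classmethod
    def _fractions_sum(cls, v):
        if v and abs(sum(r.fraction for r in v) - 1.0) > 1e-9:
            raise ValueError("rod species fractions must sum to 1")
        return v

    # -- builders ---------------------------------------------------------
    def build_params(self, replica: int = 0) -> SimulationParams:
        return self.params.build(seed=self.seed_base + replica)

    def build_vesicle(self) -> VesicleSpec:
        return self.vesicle.build()

    def build_rod_list(self) -> list[RodSpec]:
        """One RodSpec per rod at the configured density (species mixed by
        their fractions, rounded; the first species absorbs the remainder)."""
        n_total = int(round(self.density * self.vesicle.n_disks
                            * self.vesicle.disk_diameter))
        counts = [int(round(rc.fraction * n_total)) for rc in self.rods]
        counts[0] += n_total - sum(counts)
        out = []
        for rc, k in zip(self.rods, counts):
            out.extend([rc.build()] * k)
        return out

    def build_protocol(self) -> Protocol:
        return Protocol([e.build() for e in self.protocol])

    def build_thresholds(self) -> ClassifierThresholds:
        return self.thresholds.build()


def load_config(path_or_text) -> RunConfig:
    """YAML (or JSON: a YAML subset) -> RunConfig; unknown keys rejected."""
    text = Path(path_or_text).read_text() \
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text) \
        and Path(str(path_or_text)).exists() else str(path_or_text)
    data = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize with every defaulted value made explicit (round-trips)."""
    text = yaml.safe_dump(cfg.model_dump(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
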