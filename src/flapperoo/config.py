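"""Validated run configuration (YAML/JSON) for the CLI and demo pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .control_volume import ControlVolumeSpec
from .geometry import WingGeometry
from .quasi_steady import AeroModel
from .synthetic import JetSpec, SyntheticSpec

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    armwing_length: float = 0.1
    handwing_length: float = 0.1
    chord: float = 0.2
    n_elements: int = 20
    air_density: float = 1.2

    def build(self) -> WingGeometry:
        return WingGeometry(**self.model_dump())


class AeroConfig(_Strict):
    lift_slope: float = 1.7
    drag_offset: float = 0.05
    drag_slope: float = 1.7

    def build(self, freestream: float, air_density: float) -> AeroModel:
        return AeroModel(freestream=freestream, air_density=air_density,
                         **self.model_dump())


class KinematicsConfig(_Strict):
    frequency: float = 3.0
    freestream: float = 4.0
    flap_amplitude_deg: float = 44.0
    fold_amplitude_deg: float = 100.0
    fold_onset: float = 1.0 / 3.0
    phase_lag: float = 0.1
    sample_rate: float = 500.0
    n_cycles: int = 2


class ControlVolumeConfig(_Strict):
    x_min: float = -0.15
    x_max: float = 0.15
    z_min: float = -0.15
    z_max: float = 0.15
    n_bins: int = 83
    clap_window: tuple[float, float] = (0.7, 0.9)

    def build(self, jet_width: float, chord: float) -> ControlVolumeSpec:
        return ControlVolumeSpec(x_min=self.x_min, x_max=self.x_max,
                                 z_min=self.z_min, z_max=self.z_max,
                                 jet_width=jet_width, chord=chord)


class JetConfig(_Strict):
    peak_speed: float = 4.0
    core_radius: float = 0.04
    centre: tuple[float, float] = (0.0, 0.0)
    clap_window: tuple[float, float] = (0.65, 0.95)
    scoop: bool = True
    scoop_ratio: float = 0.3
    scoop_window: tuple[float, float] = (0.50, 0.70)

    def build(self) -> JetSpec:
        return JetSpec(**self.model_dump())


class SynthConfig(_Strict):
    n_cycles: int = 40
    force_rate: float = 1000.0
    power_rate: float = 512.0
    field_rate: float = 500.0
    force_noise: float = 0.05
    power_noise: float = 0.05
    velocity_noise: float = 0.05
    inertia_force: tuple[float, float] = (2.0, 0.8)
    inertia_power: tuple[float, float] = (1.5, 0.6)
    trigger_offset: float = 0.03
    jet: JetConfig = Field(default_factory=JetConfig)


class SweepConfig(_Strict):
    st_grid: list[float] = Field(default_factory=lambda: [0.21, 0.31, 0.41])
    theta0_grid_deg: list[float] = Field(
        default_factory=lambda: [0.0, 30.0, 60.0, 100.0])
    n_samples: int = 400


class RunConfig(_Strict):
    """Top-level configuration; unknown keys are rejected on load."""

    seed: int = 0
    output_dir: str = "flapperoo_out"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    aero: AeroConfig = Field(default_factory=AeroConfig)
    kinematics: KinematicsConfig = Field(default_factory=KinematicsConfig)
    control_volume: ControlVolumeConfig = Field(
        default_factory=ControlVolumeConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    sweep: SweepConfig = Field(default_factory=SweepConfig)

    def synthetic_spec(self, n_cycles: int | None = None) -> SyntheticSpec:
        kin = self.kinematics
        return SyntheticSpec(
            seed=self.seed, geometry=self.geometry.build(),
            frequency=kin.frequency, freestream=kin.freestream,
            fold_amplitude=float(np.deg2rad(kin.fold_amplitude_deg)),
            flap_amplitude=float(np.deg2rad(kin.flap_amplitude_deg)),
            fold_onset=kin.fold_onset, phase_lag=kin.phase_lag,
            n_cycles=n_cycles or self.synth.n_cycles,
            kin_sample_rate=kin.sample_rate,
            force_rate=self.synth.force_rate,
            power_rate=self.synth.power_rate,
            field_rate=self.synth.field_rate,
            force_noise=self.synth.force_noise,
            power_noise=self.synth.power_noise,
            velocity_noise=self.synth.velocity_noise,
            inertia_force=self.synth.inertia_force,
            inertia_power=self.synth.inertia_power,
            trigger_offset=self.synth.trigger_offset,
            jet=self.synth.jet.build())

    def provenance(self) -> dict:
        from . import __version__
        return {"config": self.model_dump(), "seed": self.seed,
                "version": __version__}


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON config; defaults when path is None."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") \
        else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
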