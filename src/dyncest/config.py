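"""Validated study configuration (YAML-backed) for end-to-end runs.

A :class:`StudyConfig` describes one simulated-and-analyzed study: field and
pool physics, the saturation scheme, which frequency list to run, the uptake
/ artifact / noise models for the test and control cohorts, cohort sizes,
the phantom grid, analysis windows and the global seed.  Pydantic performs
the schema validation; every pipeline run writes its resolved configuration
next to its outputs so any artifact is regenerable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from . import bmc, synth
from .schedule import TimingParams

__all__ = ["StudyConfig", "load_config"]


class PoolCfg(BaseModel):
    name: str
    delta_ppm: float
    T1_s: float = Field(gt=0)
    T2_s: float = Field(gt=0)
    fraction: float = Field(ge=0)
    k_exch_per_s: float = Field(ge=0, default=0.0)

    def build(self) -> bmc.Pool:
        return bmc.Pool(self.name, self.delta_ppm, self.T1_s, self.T2_s,
                        self.fraction, self.k_exch_per_s)


class FieldCfg(BaseModel):
    B0_T: float = 7.0
    gamma_hz_per_T: float = bmc.GAMMA_HZ_PER_T

    def build(self, drift_hz_per_min: float = 0.0) -> bmc.FieldParams:
        return bmc.FieldParams(self.B0_T, self.gamma_hz_per_T, drift_hz_per_min)


class PulseCfg(BaseModel):
    shape: Literal["cw", "block", "gaussian"] = "gaussian"
    b1_peak_uT: float = Field(ge=0, default=1.2)
    duration_s: float = Field(gt=0, default=0.030)
    truncation_sigma: float = Field(gt=0, default=2.5)

    def build(self) -> bmc.SaturationPulse:
        return bmc.SaturationPulse(self.shape, self.b1_peak_uT, self.duration_s,
                                   self.truncation_sigma)


class TimingCfg(BaseModel):
    tr_s: float = Field(gt=0, default=0.04041)
    n_spokes: int = Field(ge=1, default=302)
    sat_pulse_s: float = Field(gt=0, default=0.030)
    injection_start_min: float = Field(gt=0, default=23.0)
    injection_duration_min: float = Field(gt=0, default=1.0)

    def build(self) -> TimingParams:
        return TimingParams(self.tr_s, self.n_spokes, self.sat_pulse_s,
                            self.injection_start_min, self.injection_duration_min)


class UptakeCfg(BaseModel):
    spike_amplitude_mtr: float = Field(ge=0, default=0.0064)
    spike_peak_delay_min: float = Field(gt=0, default=7.0)
    spike_width_min: float | None = None
    accumulation_slope_mtr_per_min: float = 5e-5

    def build(self, injection_start_min: float) -> synth.UptakeModel:
        return synth.UptakeModel(injection_start_min, self.spike_amplitude_mtr,
                                 self.spike_peak_delay_min, self.spike_width_min,
                                 self.accumulation_slope_mtr_per_min)


class ArtifactCfg(BaseModel):
    drift_hz_per_min: float = 0.05
    signal_drift_frac_per_min: float = -5e-4
    motion_onset_min: float = 60.0
    motion_amplitude_mtr: float = 0.002
    motion_full_scale_min: float = 120.0

    def build(self) -> synth.ArtifactModel:
        return synth.ArtifactModel(self.drift_hz_per_min, self.signal_drift_frac_per_min,
                                   self.motion_onset_min, self.motion_amplitude_mtr,
                                   self.motion_full_scale_min)


class NoiseCfg(BaseModel):
    sigma_frac: float = Field(ge=0, default=0.005)
    distribution: Literal["rician", "gaussian"] = "rician"

    def build(self) -> synth.NoiseModel:
        return synth.NoiseModel(self.sigma_frac, self.distribution)


class StudyConfig(BaseModel):
    """Schema-validated description of a simulated dynamic CEST study."""

    seed: int = 0
    outdir: str = "study_out"
    schedule: Literal["fl1", "fl2", "fl3", "full"] = "fl1"
    n_cycles: int = Field(ge=1, default=98)
    n_test: int = Field(ge=1, default=5)
    n_control: int = Field(ge=0, default=5)
    grid: int = Field(ge=16, default=96)
    tracked_offset_ppm: float = -2.7
    alpha: float = Field(gt=0, lt=1, default=0.05)
    auc_windows_min: list[tuple[float, float]] = Field(
        default_factory=lambda: [(8, 23), (24, 39), (65, 80), (105, 120)])
    pre_window_min: tuple[float, float] | None = None

    field_params: FieldCfg = Field(default_factory=FieldCfg)
    timing: TimingCfg = Field(default_factory=TimingCfg)
    pulse: PulseCfg = Field(default_factory=PulseCfg)
    pools: list[PoolCfg] = Field(default_factory=lambda: [
        PoolCfg(name="water", delta_ppm=0.0, T1_s=1.8, T2_s=0.030, fraction=1.0),
        PoolCfg(name="thiol", delta_ppm=-2.7, T1_s=1.0, T2_s=0.020, fraction=0.0,
                k_exch_per_s=1000.0),
        PoolCfg(name="amide", delta_ppm=3.6, T1_s=1.0, T2_s=0.020, fraction=2e-4,
                k_exch_per_s=30.0),
    ])
    uptake: UptakeCfg = Field(default_factory=UptakeCfg)
    artifacts: ArtifactCfg = Field(default_factory=ArtifactCfg)
    noise: NoiseCfg = Field(default_factory=NoiseCfg)

    @model_validator(mode="after")
    def _check_pools(self) -> "StudyConfig":
        if sum(p.name == "water" for p in self.pools) != 1:
            raise ValueError("pool list must contain exactly one water pool")
        return self

    def build_pools(self) -> list[bmc.Pool]:
        return [p.build() for p in self.pools]

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def load_config(path: str | Path | None = None, **overrides) -> StudyConfig:
    """Load a StudyConfig from YAML (all keys optional) plus overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return StudyConfig(**data)
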