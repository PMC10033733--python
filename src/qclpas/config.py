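"""Run configuration: schema-validated, fully explicit, reproducible.

A run is described by one canonical YAML file; command-line flags override
individual keys and the effective merged configuration is always written
next to the outputs, so any two runs with identical config and seeds produce
byte-identical numeric artifacts.  Unknown keys are rejected.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _pkg_version
from .instrument import (
    AcousticCoefficients,
    PowerModel,
    TuningModel,
    default_acoustics,
    default_power,
    default_tuning,
)
from .synthetic import NOISE_SIGMA_SPECTRUM_UV

__all__ = ["RunConfig", "InstrumentConfig", "load_config", "write_config",
           "write_manifest", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TuningConfig(_Strict):
    t0_cm1: float
    t1_cm1_per_ma: float
    t2_cm1_per_ma2: float = 0.0
    emission_fwhm_cm1: float = 0.005

    def build(self, sweep: tuple[float, float]) -> TuningModel:
        return TuningModel(t0=self.t0_cm1, t1=self.t1_cm1_per_ma,
                           t2=self.t2_cm1_per_ma2,
                           emission_fwhm=self.emission_fwhm_cm1, sweep=sweep)


class PowerConfig(_Strict):
    threshold_ma: float
    p0_w: float
    p1_w_per_ma: float
    p2_w_per_ma2: float = 0.0

    def build(self) -> PowerModel:
        return PowerModel(threshold=self.threshold_ma, p0=self.p0_w,
                          p1=self.p1_w_per_ma, p2=self.p2_w_per_ma2)


class AcousticsConfig(_Strict):
    f_res_bs_hz: float = 5049.0
    kappa_h2o_hz_per_percent: float = 5.4
    kappa_co2_hz_per_percent: float = 15.0
    b_co2_fraction_per_percent: float = 0.0083
    q_coeff_dry_co2_fraction_per_percent: float = 0.01
    q_bs: float = 37.8

    def build(self) -> AcousticCoefficients:
        return AcousticCoefficients(
            f_res_bs=self.f_res_bs_hz, kappa_h2o=self.kappa_h2o_hz_per_percent,
            kappa_co2=self.kappa_co2_hz_per_percent,
            b_co2=self.b_co2_fraction_per_percent,
            q_coeff_dry_co2=self.q_coeff_dry_co2_fraction_per_percent,
            q_bs=self.q_bs)


class InstrumentConfig(_Strict):
    """Versioned key-value schema for the laser and acoustic-cell models."""

    schema_version: int = 1
    tuning: TuningConfig
    power: PowerConfig
    acoustics: AcousticsConfig = Field(default_factory=AcousticsConfig)

    @classmethod
    def default(cls) -> "InstrumentConfig":
        t = default_tuning()
        p = default_power()
        a = default_acoustics()
        return cls(
            tuning=TuningConfig(t0_cm1=t.t0, t1_cm1_per_ma=t.t1,
                                t2_cm1_per_ma2=t.t2,
                                emission_fwhm_cm1=t.emission_fwhm),
            power=PowerConfig(threshold_ma=p.threshold, p0_w=p.p0,
                              p1_w_per_ma=p.p1, p2_w_per_ma2=p.p2),
            acoustics=AcousticsConfig(
                f_res_bs_hz=a.f_res_bs, kappa_h2o_hz_per_percent=a.kappa_h2o,
                kappa_co2_hz_per_percent=a.kappa_co2,
                b_co2_fraction_per_percent=a.b_co2,
                q_coeff_dry_co2_fraction_per_percent=a.q_coeff_dry_co2,
                q_bs=a.q_bs))


class RunConfig(_Strict):
    """Top-level run description (sweep, lock-in, seeds, instrument)."""

    schema_version: int = 1
    seed: int = 0
    sweep_start_ma: float = 350.0
    sweep_stop_ma: float = 495.0
    sweep_step_ma: float = 1.0
    tau_s: float = 5.0
    rolloff_db_per_octave: int = 18
    sampling_rate_hz: float = 5.0
    noise_sigma_uv: float = NOISE_SIGMA_SPECTRUM_UV
    instrument: InstrumentConfig = Field(default_factory=InstrumentConfig.default)

    def sweep(self):
        import numpy as np
        if self.sweep_step_ma <= 0 or self.sweep_stop_ma <= self.sweep_start_ma:
            raise ConfigError("invalid sweep bounds/step")
        n = int(round((self.sweep_stop_ma - self.sweep_start_ma) / self.sweep_step_ma)) + 1
        return self.sweep_start_ma + self.sweep_step_ma * np.arange(n)

    def models(self):
        bounds = (self.sweep_start_ma, self.sweep_stop_ma)
        return (self.instrument.tuning.build(bounds),
                self.instrument.power.build(),
                self.instrument.acoustics.build())


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run configuration (defaults when ``path`` is None) and
    apply CLI overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError -> diagnostics
        raise ConfigError(f"invalid configuration: {exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective configuration, all defaults explicit."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


def write_manifest(path: str | Path, *, command: str, config: RunConfig,
                   outputs: list[str], extra: dict | None = None) -> None:
    """Structured run log: parameters, seeds, package version, artifacts."""
    payload = {
        "package": "qclpas",
        "version": _pkg_version,
        "command": command,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.model_dump(),
        "outputs": outputs,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
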