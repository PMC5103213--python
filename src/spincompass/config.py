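"""Run configuration: schema, validation and named presets.

A run is described by a single YAML (or JSON) document validated against the
pydantic schema below before any computation; unknown keys are rejected.
Command-line flags override config-file values, which override the preset
defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .spin_hamiltonian import SPIN_SYSTEM_PRESETS

__all__ = ["RunConfig", "RUN_PRESETS", "load_config", "config_hash"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThetaGridConfig(_StrictModel):
    """Orientation grid in degrees."""

    start: float = 0.0
    stop: float = 180.0
    step: float = Field(default=1.0, gt=0)

    def as_array(self) -> np.ndarray:
        return np.arange(self.start, self.stop + self.step / 2, self.step)


class RatesConfig(_StrictModel):
    """Reaction rate constants, s^-1."""

    k_f: float = Field(default=1e6, gt=0)
    k_r: float = Field(default=1e9, ge=0)
    r0: float = Field(default=1.0, gt=0)


class GridConfig(_StrictModel):
    """Rate-constant grids for the metric sweep."""

    k_f: list[float] = Field(default=[10.0**e for e in range(2, 7)])
    k_r: list[float] = Field(default=[10.0**e for e in range(3, 10)])

    @model_validator(mode="after")
    def _positive(self) -> "GridConfig":
        if any(v <= 0 for v in self.k_f):
            raise ValueError("k_f grid values must be positive")
        if any(v < 0 for v in self.k_r):
            raise ValueError("k_r grid values must be non-negative")
        return self


class FlightSection(_StrictModel):
    """Migration scenario; sigma_deg may list several compass precisions."""

    daily_distance_km: float = Field(default=200.0, gt=0)
    target_distance_km: float = Field(default=4700.0, gt=0)
    n_birds: int = Field(default=10000, ge=1)
    sigma_deg: list[float] = Field(default=[20.0, 45.0])
    max_days: int = Field(default=10000, ge=1)

    @model_validator(mode="after")
    def _sigmas(self) -> "FlightSection":
        if not self.sigma_deg or any(s < 0 for s in self.sigma_deg):
            raise ValueError("sigma_deg must be a non-empty list of non-negatives")
        return self


class RunConfig(_StrictModel):
    """Complete, validated run description."""

    preset: str = "reference"
    b0_tesla: float = Field(default=50e-6, ge=0)
    rates: RatesConfig = RatesConfig()
    theta: ThetaGridConfig = ThetaGridConfig()
    grid: GridConfig = GridConfig()
    flight: FlightSection = FlightSection()
    seed: int = 0
    out_dir: str = "out"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    @model_validator(mode="after")
    def _known_preset(self) -> "RunConfig":
        if self.preset not in SPIN_SYSTEM_PRESETS:
            raise ValueError(
                f"unknown spin-system preset {self.preset!r}; "
                f"available: {sorted(SPIN_SYSTEM_PRESETS)}"
            )
        return self


#: Named run presets for the standard scenarios:
#: "no_regeneration"   -- open (non-cyclic) scheme, k_r = 0: the total rate
#:                        is orientation-independent.
#: "fast_forward"      -- k_f = 1 us^-1 with fast regeneration k_r = 1 ns^-1.
#: "slow_forward"      -- k_f = 1 ms^-1, k_r = 1 ns^-1: near-limiting triplet
#:                        rate and a narrow angular response.
RUN_PRESETS: dict[str, dict] = {
    "no_regeneration": {"rates": {"k_f": 1e6, "k_r": 0.0}},
    "fast_forward": {"rates": {"k_f": 1e6, "k_r": 1e9}},
    "slow_forward": {"rates": {"k_f": 1e3, "k_r": 1e9}},
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def load_config(
    path: str | Path | None = None,
    run_preset: str | None = None,
    overrides: dict | None = None,
) -> RunConfig:
    """Assemble a RunConfig from preset < file < CLI overrides."""
    data: dict = {}
    if run_preset is not None:
        try:
            data = _deep_update(data, RUN_PRESETS[run_preset])
        except KeyError:
            raise KeyError(
                f"unknown run preset {run_preset!r}; available: {sorted(RUN_PRESETS)}"
            ) from None
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = _deep_update(data, loaded)
    if overrides:
        data = _deep_update(data, overrides)
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for provenance."""
    canonical = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
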