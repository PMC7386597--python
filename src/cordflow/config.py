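"""Run configuration: schema, baseline fixture, YAML/JSON round-trip.

Every field defaults to the baseline term-cord parameterization, so
``RunConfig()`` is the reference scenario and a config file only needs to
mention what it changes. Velocities and temperatures accept unit-suffixed
strings (``"61.18 cm/s"``, ``"37.5 C"``); geometric lengths likewise
(``"8.3 mm"``). Everything is stored in SI internally (velocities m/s,
lengths m) except physiological temperatures, which are kept in °C.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, field_validator

from .geometry import CordSpec
from .physiology import (
    UA_INLET_TEMPERATURE_C,
    UA_INLET_VELOCITY,
    UA_OUTLET_VELOCITY,
    UV_INLET_VELOCITY,
    UV_OUTLET_VELOCITY,
    BloodModel,
    FetalParams,
)
from .pipeflow import SolverOptions
from .units import parse_temperature_celsius, parse_velocity

__all__ = ["RunConfig", "load_config", "save_config", "generate_baseline_config"]


class RunConfig(BaseModel):
    """Full description of one scenario run."""

    label: str = "baseline"
    cord: CordSpec = CordSpec()
    blood: BloodModel = BloodModel()
    fetal: FetalParams = FetalParams()
    solver: SolverOptions = SolverOptions()
    points_per_coil: int = 64
    circumferential_segments: int = 64
    # boundary values; uv_inlet is "reported", "maternal_model", or a °C value
    uv_inlet: float | str = "reported"
    ua_inlet_temperature: float = UA_INLET_TEMPERATURE_C
    ua_inlet_velocity: float = UA_INLET_VELOCITY
    uv_inlet_velocity: float = UV_INLET_VELOCITY
    ua_outlet_velocity: float = UA_OUTLET_VELOCITY
    uv_outlet_velocity: float = UV_OUTLET_VELOCITY

    @field_validator(
        "ua_inlet_velocity", "uv_inlet_velocity",
        "ua_outlet_velocity", "uv_outlet_velocity", mode="before",
    )
    @classmethod
    def _coerce_velocity(cls, v):
        return parse_velocity(v) if v is not None else v

    @field_validator("ua_inlet_temperature", mode="before")
    @classmethod
    def _coerce_temperature(cls, v):
        return parse_temperature_celsius(v) if v is not None else v

    @field_validator("uv_inlet", mode="before")
    @classmethod
    def _coerce_uv_inlet(cls, v):
        if isinstance(v, str) and v in ("reported", "maternal_model"):
            return v
        return parse_temperature_celsius(v)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON — YAML is a superset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**(data or {}))


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = config.model_dump(mode="json")
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            yaml.safe_dump(data, fh, sort_keys=True)


def generate_baseline_config(path: str | Path) -> RunConfig:
    """Emit the baseline scenario as a config file and return it."""
    config = RunConfig()
    save_config(config, path)
    return config
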