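"""Physiological parameterization and boundary-condition derivation.

The thermal boundary conditions follow a simple whole-body energy argument:
a term fetus produces metabolic heat at ~3.5 W/kg and holds a standing
0.5 °C excess over the maternal core ("heat clump"), which fixes the total
fetal-maternal heat conductance at 7 W/(kg·°C). Distributing the implied heat
power over each vessel's lateral wall area, scaled by the temperature
difference between the intra-amniotic space and the blood in that vessel,
yields constant wall heat fluxes per vessel:

    q'' = H_cond * FW * dT / A_w

The umbilical-vein inlet temperature (placental end) is not measurable; it is
estimated with a maternal-vessel sub-model — a straight tube of placental
thickness carrying maternal blood at core temperature, heated through its wall
by the same conductance argument. The baseline adopts 37.212 °C for that
inlet, the value the sub-model is reported to produce; re-deriving it from the
closed-form energy balance gives 37.183 °C with a standard blood specific heat
(3617 J/kg/K), and matches 37.212 °C only for cp ≈ 3117 J/kg/K (see
``invert_cp_for_outlet_temperature``).

Sign convention: wall heat flux is positive when heat flows INTO the lumen,
so its sign always equals the sign of the driving temperature difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from pydantic import BaseModel, field_validator, model_validator

from .geometry import CordGeometry, CordSpec, lateral_tube_area
from .units import celsius_to_kelvin, parse_temperature_celsius, parse_velocity

__all__ = [
    "BloodModel",
    "FetalParams",
    "ThermalBC",
    "FlowBC",
    "LAMINAR_REYNOLDS_LIMIT",
    "UA_INLET_VELOCITY",
    "UV_INLET_VELOCITY",
    "UA_OUTLET_VELOCITY",
    "UV_OUTLET_VELOCITY",
    "UA_INLET_TEMPERATURE_C",
    "REPORTED_UV_INLET_TEMPERATURE_C",
    "MATERNAL_VESSEL_LENGTH",
    "MATERNAL_VESSEL_DIAMETER",
    "MATERNAL_VESSEL_WALL_AREA",
    "MATERNAL_INLET_PRESSURE_PA",
    "heat_conductance",
    "reynolds",
    "is_laminar",
    "wall_heat_flux",
    "thermal_deltas",
    "maternal_vessel_outlet_temperature",
    "invert_cp_for_outlet_temperature",
    "build_boundary_conditions",
]

LAMINAR_REYNOLDS_LIMIT = 2300.0

# Baseline Doppler-derived mean velocities (m/s).
UA_INLET_VELOCITY = 0.6118
UV_INLET_VELOCITY = 0.3059
UA_OUTLET_VELOCITY = 0.3589
UV_OUTLET_VELOCITY = 0.1795

UA_INLET_TEMPERATURE_C = 37.5
#: UV inlet temperature (°C) as produced by the maternal-vessel sub-model in
#: the baseline parameterization; see module docstring for the re-derivation.
REPORTED_UV_INLET_TEMPERATURE_C = 37.212

#: Maternal vessel: straight tube through a placental mass of 0.04 m thickness.
MATERNAL_VESSEL_LENGTH = 0.04
#: The maternal vessel diameter is not independently constrained; 8.3 mm (the
#: UV diameter) is adopted, which gives a lateral area pi*D*L = 0.00104 m^2,
#: consistent with the quoted 0.00103 m^2 (itself implying D ~ 8.2 mm).
MATERNAL_VESSEL_DIAMETER = 0.0083
#: Wall area (m^2) the baseline maternal wall flux 11,213.6 W/m^2 is
#: normalized by, kept as quoted so flux * area returns the sub-model's wall
#: power H_cond * FW * dT_mf = 11.55 W exactly.
MATERNAL_VESSEL_WALL_AREA = 0.00103
MATERNAL_INLET_PRESSURE_PA = 70 * 133.322387415


class BloodModel(BaseModel):
    """Constant-property Newtonian blood.

    density 1056 kg/m^3 and dynamic viscosity 0.004 Pa*s are the umbilical
    baseline; specific heat defaults to the standard human-blood 3617 J/kg/K
    and the entropy reference temperature to 298.15 K (both configurable —
    neither is pinned down by the umbilical literature).
    """

    density: float = 1056.0
    dynamic_viscosity: float = 0.004
    specific_heat: float = 3617.0
    entropy_ref_temperature: float = 298.15

    @model_validator(mode="after")
    def _positive(self):
        for name in ("density", "dynamic_viscosity", "specific_heat",
                     "entropy_ref_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self


class FetalParams(BaseModel):
    """Fetal / maternal thermal set-points for a 39-week fetus.

    Temperatures are in °C. The intra-amniotic temperature is the fetal core
    (37.5 °C) minus 0.2 °C; the maternal core is 37.0 °C.
    """

    fetal_weight: float = 3.3
    metabolic_heat_rate: float = 3.5
    maternal_fetal_delta: float = 0.5
    intraamniotic_temperature: float = 37.3
    maternal_core_temperature: float = 37.0

    @field_validator("intraamniotic_temperature", "maternal_core_temperature",
                     mode="before")
    @classmethod
    def _coerce_temp(cls, v):
        return parse_temperature_celsius(v) if v is not None else v

    @model_validator(mode="after")
    def _validate(self):
        if self.fetal_weight <= 0:
            raise ValueError("fetal_weight must be positive")
        if self.maternal_fetal_delta <= 0:
            raise ValueError("maternal_fetal_delta must be positive")
        return self


@dataclass
class ThermalBC:
    """Thermal boundary condition for one vessel.

    ``wall_heat_flux`` is signed (positive = heat into the lumen) and carries
    the same sign as ``delta_T``, the temperature difference it was derived
    from. ``inlet_temperature`` is in Kelvin. ``wall_area`` records the area
    the flux was normalized by, so that flux * area recovers the vessel's
    total wall power exactly.
    """

    vessel_id: str
    wall_heat_flux: float
    delta_T: float
    inlet_temperature: float
    wall_area: float | None = None

    def __post_init__(self):
        if self.delta_T * self.wall_heat_flux < 0:
            raise ValueError("wall_heat_flux must carry the sign of delta_T")


@dataclass
class FlowBC:
    """Flow boundary condition for one vessel (mean velocities, m/s)."""

    vessel_id: str
    inlet_mean_velocity: float
    outlet_mean_velocity: float | None = None
    outlet_pressure: float | None = None
    flow_direction: Literal["fetal_to_placental", "placental_to_fetal"] = (
        "fetal_to_placental"
    )

    def __post_init__(self):
        # zero is tolerated so the no-flow pressure limit can be exercised;
        # the temperature solver rejects it separately.
        if self.inlet_mean_velocity < 0:
            raise ValueError("inlet_mean_velocity must be non-negative")


def heat_conductance(metabolic_heat_rate: float, maternal_fetal_delta: float) -> float:
    """Total fetal-maternal heat conductance, W/(kg·°C).

    The fetus sheds its metabolic heat across the standing maternal-fetal
    temperature difference, so the conductance is simply their quotient:
    3.5 W/kg over 0.5 °C gives 7 W/(kg·°C).
    """
    if maternal_fetal_delta == 0:
        raise ZeroDivisionError("maternal_fetal_delta must be nonzero")
    return metabolic_heat_rate / maternal_fetal_delta


def reynolds(blood: BloodModel, diameter: float, mean_velocity: float) -> float:
    """Pipe Reynolds number rho*U*D/mu."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if mean_velocity < 0:
        raise ValueError("mean_velocity must be non-negative")
    return blood.density * mean_velocity * diameter / blood.dynamic_viscosity


def is_laminar(re: float) -> bool:
    """Laminar classification at the conventional pipe threshold Re < 2300."""
    return re < LAMINAR_REYNOLDS_LIMIT


def wall_heat_flux(
    conductance: float, fetal_weight: float, delta_T: float, wall_area: float
) -> float:
    """Constant wall heat flux q'' = H_cond * FW * dT / A_w, W/m^2 (signed)."""
    if wall_area <= 0:
        raise ValueError("wall_area must be positive")
    return conductance * fetal_weight * delta_T / wall_area


def thermal_deltas(
    intraamniotic: float, t_uv_in: float, t_ua_in: float
) -> tuple[float, float]:
    """Driving temperature differences (°C) for the UV and UA wall fluxes.

    dT1 = T_amniotic - T_UV,in (baseline 37.3 - 37.212 = 0.088 °C, heat into
    the vein) and dT2 = T_amniotic - T_UA,in (37.3 - 37.5 = -0.2 °C, heat out
    of the arteries).
    """
    return intraamniotic - t_uv_in, intraamniotic - t_ua_in


def maternal_vessel_outlet_temperature(
    blood: BloodModel,
    fetal: FetalParams,
    tube_length: float = MATERNAL_VESSEL_LENGTH,
    tube_diameter: float = MATERNAL_VESSEL_DIAMETER,
    inlet_temperature: float | None = None,
    mean_velocity: float = UV_INLET_VELOCITY,
) -> float:
    """Outlet temperature (°C) of the maternal-vessel sub-model.

    Steady energy balance on a straight tube whose wall flux comes from the
    conductance argument at the full maternal-fetal difference (the placenta
    runs 0.5 °C above maternal core):

        T_out = T_in + q'' * (pi*D*L) / (m_dot * cp)

    with q'' = H_cond*FW*dT_mf / (pi*D*L), so the wall power cancels the area
    and T_out - T_in = H_cond*FW*dT_mf / (m_dot*cp).
    """
    if tube_length <= 0 or tube_diameter <= 0:
        raise ValueError("tube dimensions must be positive")
    if mean_velocity <= 0:
        raise ValueError("mean_velocity must be positive (zero flow undefined)")
    if inlet_temperature is None:
        inlet_temperature = fetal.maternal_core_temperature
    area_w = lateral_tube_area(tube_diameter, tube_length)
    h = heat_conductance(fetal.metabolic_heat_rate, fetal.maternal_fetal_delta)
    q_flux = wall_heat_flux(h, fetal.fetal_weight, fetal.maternal_fetal_delta, area_w)
    m_dot = blood.density * mean_velocity * math.pi * tube_diameter**2 / 4.0
    return inlet_temperature + q_flux * area_w / (m_dot * blood.specific_heat)


def invert_cp_for_outlet_temperature(
    blood: BloodModel,
    fetal: FetalParams,
    target_outlet: float,
    tube_length: float = MATERNAL_VESSEL_LENGTH,
    tube_diameter: float = MATERNAL_VESSEL_DIAMETER,
    inlet_temperature: float | None = None,
    mean_velocity: float = UV_INLET_VELOCITY,
) -> float:
    """Specific heat (J/kg/K) that makes the sub-model hit ``target_outlet``.

    Algebraic inversion of the closed-form balance: cp = Q / (m_dot * dT_out).
    Useful to characterize what effective cp a quoted outlet temperature
    implies (37.212 °C corresponds to cp ≈ 3117 J/kg/K at baseline).
    """
    if inlet_temperature is None:
        inlet_temperature = fetal.maternal_core_temperature
    rise = target_outlet - inlet_temperature
    if rise <= 0:
        raise ValueError("target_outlet must exceed the inlet temperature")
    h = heat_conductance(fetal.metabolic_heat_rate, fetal.maternal_fetal_delta)
    power = h * fetal.fetal_weight * fetal.maternal_fetal_delta
    m_dot = blood.density * mean_velocity * math.pi * tube_diameter**2 / 4.0
    return power / (m_dot * rise)


def build_boundary_conditions(
    spec: CordSpec,
    blood: BloodModel,
    fetal: FetalParams,
    geometry: CordGeometry,
    uv_inlet: float | str = "reported",
    ua_inlet_velocity: float | str = UA_INLET_VELOCITY,
    uv_inlet_velocity: float | str = UV_INLET_VELOCITY,
    ua_outlet_velocity: float | str | None = UA_OUTLET_VELOCITY,
    uv_outlet_velocity: float | str | None = UV_OUTLET_VELOCITY,
    ua_inlet_temperature: float | str = UA_INLET_TEMPERATURE_C,
) -> dict[str, tuple[ThermalBC, FlowBC]]:
    """Assemble per-vessel thermal and flow boundary conditions.

    The arteries enter at the fetal end at the fetal core temperature and flow
    toward the placenta; the vein flows the opposite way, entering at the
    placental end at the maternal sub-model temperature. Wall fluxes use the
    straight-length wall areas carried by ``geometry``.

    ``uv_inlet`` selects the UV inlet temperature: ``"reported"`` (default)
    adopts 37.212 °C, ``"maternal_model"`` recomputes it from the closed-form
    sub-model with the supplied blood cp, and a float (°C) overrides it.
    """
    if not geometry.wall_areas:
        raise ValueError("geometry has no wall areas; build it first")
    ua_u_in = parse_velocity(ua_inlet_velocity)
    uv_u_in = parse_velocity(uv_inlet_velocity)
    ua_u_out = None if ua_outlet_velocity is None else parse_velocity(ua_outlet_velocity)
    uv_u_out = None if uv_outlet_velocity is None else parse_velocity(uv_outlet_velocity)
    t_ua_in = parse_temperature_celsius(ua_inlet_temperature)

    if uv_inlet == "reported":
        t_uv_in = REPORTED_UV_INLET_TEMPERATURE_C
    elif uv_inlet == "maternal_model":
        t_uv_in = maternal_vessel_outlet_temperature(blood, fetal)
    else:
        t_uv_in = parse_temperature_celsius(uv_inlet)

    d_t1, d_t2 = thermal_deltas(fetal.intraamniotic_temperature, t_uv_in, t_ua_in)
    h = heat_conductance(fetal.metabolic_heat_rate, fetal.maternal_fetal_delta)

    bcs: dict[str, tuple[ThermalBC, FlowBC]] = {}
    for vid in geometry.centerlines:
        area = geometry.wall_areas[vid]
        if vid == "UV":
            flux = wall_heat_flux(h, fetal.fetal_weight, d_t1, area)
            thermal = ThermalBC(vid, flux, d_t1, celsius_to_kelvin(t_uv_in), area)
            flow = FlowBC(vid, uv_u_in, uv_u_out, 0.0, "placental_to_fetal")
        else:
            flux = wall_heat_flux(h, fetal.fetal_weight, d_t2, area)
            thermal = ThermalBC(vid, flux, d_t2, celsius_to_kelvin(t_ua_in), area)
            flow = FlowBC(vid, ua_u_in, ua_u_out, 0.0, "fetal_to_placental")
        bcs[vid] = (thermal, flow)
    return bcs
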