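"""Reduced-order steady solver for a single cord vessel.

Each vessel is treated as a rigid circular tube of constant diameter carrying
steady, laminar, incompressible blood flow. Along the centreline arc length s:

* pressure integrates the Darcy friction gradient dp/ds = -f * rho*U^2 / (2D),
  with f = 64/Re for a straight tube and a Dean-number correction (White's or
  Ito's laminar curved-pipe correlation) for the helical arteries;
* temperature obeys a first-order upwind finite-volume energy balance
  m_dot * cp * dT/ds = q' where q' is the wall heating per unit length; the
  per-vessel wall power q'' * A_w is distributed uniformly along the solved
  arc length, which makes the discrete balance m_dot*cp*(T_out - T_in) =
  q''*A_w exact to round-off whatever wall-area convention produced q'';
* wall shear rate is the Poiseuille value 8U/D and static entropy the
  incompressible-fluid expression cp*ln(T/T_ref).

Two velocity modes exist. ``mass_conservative`` (default) keeps U constant at
the inlet value, as continuity demands in a rigid constant-area tube.
``prescribed_taper`` linearly tapers U from the prescribed inlet to the
prescribed outlet mean velocity; it deliberately violates mass conservation
and exists only to mimic decelerating reference profiles for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, model_validator

from .geometry import CordGeometry
from .physiology import (
    BloodModel,
    FlowBC,
    ThermalBC,
    is_laminar,
    reynolds,
)

__all__ = [
    "AxialGrid",
    "SolverOptions",
    "VesselSolution",
    "make_grid",
    "dean_number",
    "friction_factor",
    "solve_pressure",
    "solve_temperature",
    "wall_shear_rate",
    "static_entropy",
    "solve_vessel",
]


@dataclass
class AxialGrid:
    """Uniform 1D finite-volume grid along a vessel's arc length."""

    vessel_id: str
    n_cells: int
    cell_arclength_centers: np.ndarray
    cell_lengths: np.ndarray

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")

    @property
    def total_length(self) -> float:
        return float(self.cell_lengths.sum())

    @property
    def face_arclengths(self) -> np.ndarray:
        """Arc length of the n_cells + 1 cell faces, from 0 to total_length."""
        return np.concatenate([[0.0], np.cumsum(self.cell_lengths)])


def make_grid(vessel_id: str, total_length: float, n_cells: int = 600) -> AxialGrid:
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    dl = total_length / n_cells
    centers = (np.arange(n_cells) + 0.5) * dl
    return AxialGrid(vessel_id, n_cells, centers, np.full(n_cells, dl))


class SolverOptions(BaseModel):
    """Options for the reduced vessel solver."""

    velocity_mode: Literal["mass_conservative", "prescribed_taper"] = (
        "mass_conservative"
    )
    friction_model: Literal["straight_laminar", "white_helical", "ito_helical"] = (
        "white_helical"
    )
    include_gravity: bool = False
    tolerance_rel: float = 1e-9
    n_cells: int = 600

    @model_validator(mode="after")
    def _validate(self):
        if self.tolerance_rel <= 0:
            raise ValueError("tolerance_rel must be positive")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        return self


@dataclass
class VesselSolution:
    """Axial profiles for one vessel, sampled at the grid cell faces.

    All arrays have n_cells + 1 entries; ``arclength`` runs from 0 at the
    vessel inlet to the solved arc length at the outlet (i.e. the coordinate
    follows the flow).
    """

    grid: AxialGrid
    arclength: np.ndarray
    mean_velocity: np.ndarray
    pressure: np.ndarray
    temperature: np.ndarray
    wall_shear_rate: np.ndarray
    static_entropy: np.ndarray
    dean_number: float
    mass_flow: float
    reynolds: float

    @property
    def pressure_drop(self) -> float:
        return float(self.pressure[0] - self.pressure[-1])

    @property
    def temperature_change(self) -> float:
        """Outlet minus inlet temperature (K); negative when the blood cools."""
        return float(self.temperature[-1] - self.temperature[0])


def dean_number(re: float, tube_diameter: float, helix_radius: float) -> float:
    """Dean number De = Re * sqrt(D / (2 R_h)); zero for a straight vessel."""
    if helix_radius <= 0 or not math.isfinite(helix_radius):
        return 0.0
    return re * math.sqrt(tube_diameter / (2.0 * helix_radius))


def friction_factor(
    re: float,
    dean: float = 0.0,
    model: Literal["straight_laminar", "white_helical", "ito_helical"] = (
        "straight_laminar"
    ),
) -> float:
    """Darcy friction factor for laminar pipe flow, optionally Dean-corrected.

    ``straight_laminar`` is the Hagen-Poiseuille 64/Re. ``white_helical``
    applies White's (1929) laminar curved-pipe multiplier

        f_c / f_s = [1 - (1 - (11.6/De)^0.45)^(1/0.45)]^(-1),   De > 11.6,

    and ``ito_helical`` Ito's (1959) laminar correlation

        f_c / f_s = 21.5 De / (1.56 + log10 De)^5.73,           De > 13.5.

    Below each correlation's validity threshold the straight value is used;
    both multipliers are >= 1 and tend to 1 as De -> 0.
    """
    if re <= 0:
        raise ValueError("Reynolds number must be positive")
    f_straight = 64.0 / re
    if model == "straight_laminar" or dean <= 0:
        return f_straight
    if model == "white_helical":
        if dean <= 11.6:
            return f_straight
        inner = 1.0 - (11.6 / dean) ** 0.45
        ratio = 1.0 / (1.0 - inner ** (1.0 / 0.45))
        return f_straight * max(ratio, 1.0)
    if model == "ito_helical":
        if dean <= 13.5:
            return f_straight
        ratio = 21.5 * dean / (1.56 + math.log10(dean)) ** 5.73
        return f_straight * max(ratio, 1.0)
    raise ValueError(f"unknown friction model {model!r}")


def _velocity_profile(
    grid: AxialGrid, flowbc: FlowBC, options: SolverOptions
) -> np.ndarray:
    s = grid.face_arclengths
    if options.velocity_mode == "mass_conservative" or flowbc.outlet_mean_velocity is None:
        return np.full_like(s, flowbc.inlet_mean_velocity)
    u_in, u_out = flowbc.inlet_mean_velocity, flowbc.outlet_mean_velocity
    return u_in + (u_out - u_in) * s / s[-1]


def solve_pressure(
    grid: AxialGrid,
    blood: BloodModel,
    flowbc: FlowBC,
    options: SolverOptions | None = None,
    *,
    diameter: float,
    helix_radius: float = 0.0,
) -> np.ndarray:
    """Axial pressure profile at cell faces (Pa), anchored at the outlet.

    Integrates dp/ds = -f(Re, De) * rho*U^2 / (2D) cell by cell; the outlet
    face is pinned to ``flowbc.outlet_pressure`` (0 Pa reference by default)
    and pressure rises upstream. Zero flow returns a uniform profile.
    """
    options = options or SolverOptions()
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    p_out = flowbc.outlet_pressure if flowbc.outlet_pressure is not None else 0.0
    u_faces = _velocity_profile(grid, flowbc, options)
    u_cells = 0.5 * (u_faces[:-1] + u_faces[1:])
    grads = np.zeros(grid.n_cells)
    for i, u in enumerate(u_cells):
        if u <= 0:
            continue
        re = reynolds(blood, diameter, u)
        de = dean_number(re, diameter, helix_radius)
        f = friction_factor(re, de, options.friction_model)
        grads[i] = f * blood.density * u * u / (2.0 * diameter)
    # integrate upstream from the outlet face
    drops = grads * grid.cell_lengths
    p = np.empty(grid.n_cells + 1)
    p[-1] = p_out
    p[:-1] = p_out + np.cumsum(drops[::-1])[::-1]
    return p


def solve_temperature(
    grid: AxialGrid,
    blood: BloodModel,
    thermalbc: ThermalBC,
    flowbc: FlowBC,
    options: SolverOptions | None = None,
    *,
    diameter: float,
) -> np.ndarray:
    """Axial temperature at cell faces (K) by upwind finite-volume marching.

    The wall power is q'' * A_w (A_w = pi*D*L_grid when the boundary condition
    carries no explicit area), spread uniformly over the grid, so each cell
    adds Q_cell / (m_dot * cp) to the advected temperature. For constant flux
    and velocity this reproduces the closed form
    T(s) = T_in + q''*pi*D*s/(m_dot*cp) exactly.
    """
    options = options or SolverOptions()
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    u_faces = _velocity_profile(grid, flowbc, options)
    if np.any(u_faces <= 0):
        raise ValueError("zero or negative mass flow; temperature undefined")
    area_cs = math.pi * diameter**2 / 4.0
    length = grid.total_length
    wall_area = (
        thermalbc.wall_area
        if thermalbc.wall_area is not None
        else math.pi * diameter * length
    )
    total_power = thermalbc.wall_heat_flux * wall_area
    q_per_len = total_power / length

    t = np.empty(grid.n_cells + 1)
    t[0] = thermalbc.inlet_temperature
    u_cells = 0.5 * (u_faces[:-1] + u_faces[1:])
    m_dots = blood.density * u_cells * area_cs
    dt = q_per_len * grid.cell_lengths / (m_dots * blood.specific_heat)
    t[1:] = t[0] + np.cumsum(dt)
    return t


def wall_shear_rate(mean_velocity: float | np.ndarray, diameter: float):
    """Poiseuille wall shear rate 8U/D (1/s)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return 8.0 * np.asarray(mean_velocity, float) / diameter


def static_entropy(temperature: float | np.ndarray, blood: BloodModel):
    """Incompressible-fluid specific entropy s = cp * ln(T/T_ref), J/(kg·K)."""
    t = np.asarray(temperature, float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (K)")
    return blood.specific_heat * np.log(t / blood.entropy_ref_temperature)


def solve_vessel(
    geometry: CordGeometry,
    blood: BloodModel,
    thermalbc: ThermalBC,
    flowbc: FlowBC,
    options: SolverOptions | None = None,
    grid: AxialGrid | None = None,
) -> VesselSolution:
    """Solve one vessel and assemble all axial profiles.

    The vessel id is taken from the boundary conditions; its diameter, arc
    length and (for arteries) helix radius come from the geometry. Warns when
    the inlet Reynolds number leaves the laminar regime the model assumes.
    """
    vid = thermalbc.vessel_id
    if vid != flowbc.vessel_id:
        raise ValueError(
            f"mismatched boundary conditions: {vid!r} vs {flowbc.vessel_id!r}"
        )
    options = options or SolverOptions()
    cl = geometry.centerline(vid)
    diameter = 2.0 * cl.tube_radius
    helix_radius = geometry.helix_radius if vid.startswith("UA") else 0.0
    if grid is None:
        grid = make_grid(vid, geometry.arc_lengths[vid], options.n_cells)

    re_in = reynolds(blood, diameter, flowbc.inlet_mean_velocity)
    if not is_laminar(re_in):
        warnings.warn(
            f"{vid}: inlet Reynolds {re_in:.0f} >= 2300; "
            "laminar model outside its regime",
            stacklevel=2,
        )

    u = _velocity_profile(grid, flowbc, options)
    p = solve_pressure(grid, blood, flowbc, options,
                       diameter=diameter, helix_radius=helix_radius)
    t = solve_temperature(grid, blood, thermalbc, flowbc, options,
                          diameter=diameter)
    gamma = wall_shear_rate(u, diameter)
    s_ent = static_entropy(t, blood)
    area_cs = math.pi * diameter**2 / 4.0
    return VesselSolution(
        grid=grid,
        arclength=grid.face_arclengths,
        mean_velocity=u,
        pressure=p,
        temperature=t,
        wall_shear_rate=gamma,
        static_entropy=s_ent,
        dean_number=dean_number(re_in, diameter, helix_radius),
        mass_flow=blood.density * flowbc.inlet_mean_velocity * area_cs,
        reynolds=re_in,
    )
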