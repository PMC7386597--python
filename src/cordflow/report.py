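"""Scenario running, sweeping, summary serialization and verification.

``run_scenario`` executes the full chain — geometry, boundary conditions,
per-vessel reduced solve — and condenses it into a ``SummaryReport`` (plus
optional CSV/JSON files). ``sweep_scenarios`` repeats that over a cartesian
parameter grid. ``percent_difference`` is the symmetric, mean-based grid
convergence statistic. ``run_verification`` executes the analytic validation
suite (Reynolds numbers, heat fluxes, Poiseuille laws, Graetz/Nusselt, energy
conservation) and reports pass/fail per check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import graetz as gz
from . import physiology as phys
from . import pipeflow as pf
from .config import RunConfig
from .geometry import build_cord_geometry
from .units import kelvin_to_celsius

__all__ = [
    "SummaryReport",
    "percent_difference",
    "run_scenario",
    "sweep_scenarios",
    "run_verification",
]


@dataclass
class SummaryReport:
    """Condensed per-vessel endpoint values for one scenario run."""

    label: str
    uci: float
    n_coils: float
    helix_radius: float
    placental_delta_t_c: float  # UA outlet minus UV inlet, °C, placental end
    vessels: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "uci_coils_per_cm": self.uci,
            "n_coils": self.n_coils,
            "helix_radius_m": self.helix_radius,
            "placental_delta_t_c": self.placental_delta_t_c,
            "vessels": self.vessels,
        }


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference |a - b| / mean(a, b) * 100.

    This mean-based convention is the grid-convergence statistic used to
    compare sparse- and dense-mesh endpoint values; it is symmetric in its
    arguments and invariant to rescaling both.
    """
    mean = (a + b) / 2.0
    if mean == 0:
        raise ZeroDivisionError("percent difference undefined when a + b = 0")
    return abs(a - b) / mean * 100.0


def _vessel_summary(sol: pf.VesselSolution, thermal: phys.ThermalBC) -> dict[str, float]:
    return {
        "inlet_velocity_m_s": float(sol.mean_velocity[0]),
        "outlet_velocity_m_s": float(sol.mean_velocity[-1]),
        "inlet_pressure_pa": float(sol.pressure[0]),
        "outlet_pressure_pa": float(sol.pressure[-1]),
        "pressure_drop_pa": sol.pressure_drop,
        "inlet_temperature_k": float(sol.temperature[0]),
        "outlet_temperature_k": float(sol.temperature[-1]),
        "temperature_change_k": sol.temperature_change,
        "reynolds": sol.reynolds,
        "dean_number": sol.dean_number,
        "wall_heat_flux_w_m2": thermal.wall_heat_flux,
        "mass_flow_kg_s": sol.mass_flow,
        "inlet_wall_shear_rate_1_s": float(sol.wall_shear_rate[0]),
        "inlet_static_entropy_j_kg_k": float(sol.static_entropy[0]),
        "outlet_static_entropy_j_kg_k": float(sol.static_entropy[-1]),
        "arc_length_m": float(sol.arclength[-1]),
    }


def run_scenario(
    config: RunConfig, output_dir: str | Path | None = None
) -> SummaryReport:
    """Run one scenario end to end: geometry -> BCs -> vessel solves.

    When ``output_dir`` is given, writes ``profiles.csv`` (axial profiles of
    every vessel, positions mapped to the cord axis with 0 = fetal end) and a
    deterministic ``summary.json``. Any stage failure is re-raised with the
    stage name prefixed.
    """
    try:
        geometry = build_cord_geometry(config.cord, config.points_per_coil)
    except Exception as exc:
        raise RuntimeError(f"geometry stage failed: {exc}") from exc
    try:
        bcs = phys.build_boundary_conditions(
            config.cord, config.blood, config.fetal, geometry,
            uv_inlet=config.uv_inlet,
            ua_inlet_velocity=config.ua_inlet_velocity,
            uv_inlet_velocity=config.uv_inlet_velocity,
            ua_outlet_velocity=config.ua_outlet_velocity,
            uv_outlet_velocity=config.uv_outlet_velocity,
            ua_inlet_temperature=config.ua_inlet_temperature,
        )
    except Exception as exc:
        raise RuntimeError(f"boundary-condition stage failed: {exc}") from exc

    solutions: dict[str, pf.VesselSolution] = {}
    vessels: dict[str, dict[str, float]] = {}
    for vid, (thermal, flow) in bcs.items():
        try:
            sol = pf.solve_vessel(geometry, config.blood, thermal, flow,
                                  config.solver)
        except Exception as exc:
            raise RuntimeError(f"solver stage failed for {vid}: {exc}") from exc
        solutions[vid] = sol
        vessels[vid] = _vessel_summary(sol, thermal)

    # placental end: UA outlet (end of arterial flow) vs UV inlet (start of
    # venous flow), both in °C.
    ua_out_c = kelvin_to_celsius(vessels["UA1"]["outlet_temperature_k"]) \
        if "UA1" in vessels else math.nan
    uv_in_c = kelvin_to_celsius(vessels["UV"]["inlet_temperature_k"])
    report = SummaryReport(
        label=config.label,
        uci=geometry.uci,
        n_coils=geometry.n_coils,
        helix_radius=geometry.helix_radius,
        placental_delta_t_c=ua_out_c - uv_in_c,
        vessels=vessels,
    )

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        _write_profiles(solutions, geometry.spec.cord_length,
                        output_dir / "profiles.csv")
        with open(output_dir / "summary.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _write_profiles(
    solutions: dict[str, pf.VesselSolution], cord_length: float, path: Path
) -> None:
    frames = []
    for vid, sol in solutions.items():
        s = sol.arclength
        frac = s / s[-1]
        if vid == "UV":
            # venous flow runs placental (x = L) to fetal (x = 0)
            x = cord_length * (1.0 - frac)
        else:
            x = cord_length * frac
        frames.append(
            pd.DataFrame(
                {
                    "cord_position_m": x,
                    "vessel_id": vid,
                    "mean_velocity": sol.mean_velocity,
                    "pressure": sol.pressure,
                    "temperature": sol.temperature,
                    "wall_shear_rate": sol.wall_shear_rate,
                    "static_entropy": sol.static_entropy,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _set_by_path(data: dict, dotted: str, value: Any) -> None:
    keys = dotted.split(".")
    node = data
    for key in keys[:-1]:
        node = node[key]
    node[keys[-1]] = value


def sweep_scenarios(
    base: RunConfig, parameter_grid: dict[str, list]
) -> pd.DataFrame:
    """Cartesian sweep over dotted parameter paths (e.g. ``cord.coil_pitch``).

    Returns one row per combination in a stable (itertools.product) order.
    Rows whose configuration is invalid or whose run fails carry the error
    message in the ``error`` column; the sweep continues.
    """
    import itertools

    if not parameter_grid:
        raise ValueError("parameter_grid must contain at least one parameter")
    names = list(parameter_grid)
    rows = []
    for combo in itertools.product(*(parameter_grid[n] for n in names)):
        row: dict[str, Any] = dict(zip(names, combo))
        try:
            data = base.model_dump()
            for name, value in zip(names, combo):
                _set_by_path(data, name, value)
            config = RunConfig(**data)
            rep = run_scenario(config)
            row.update(
                uci_coils_per_cm=rep.uci,
                n_coils=rep.n_coils,
                placental_delta_t_c=rep.placental_delta_t_c,
            )
            for vid, v in rep.vessels.items():
                row[f"{vid}_pressure_drop_pa"] = v["pressure_drop_pa"]
                row[f"{vid}_temperature_change_k"] = v["temperature_change_k"]
            row["error"] = ""
        except Exception as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_verification(config: RunConfig | None = None) -> list[dict[str, Any]]:
    """Analytic validation suite; returns one record per check.

    Each record has ``check``, ``computed``, ``expected``, ``rel_tol`` and
    ``passed``. The expected values are closed forms (Hagen-Poiseuille,
    Graetz 48/11, exact energy balance) or the baseline derivation chain.
    """
    config = config or RunConfig()
    blood, fetal = config.blood, config.fetal
    checks: list[dict[str, Any]] = []

    def add(name, computed, expected, rel_tol):
        scale = max(abs(expected), 1e-300)
        checks.append(
            {
                "check": name,
                "computed": float(computed),
                "expected": float(expected),
                "rel_tol": rel_tol,
                "passed": bool(abs(computed - expected) <= rel_tol * scale),
            }
        )

    h = phys.heat_conductance(fetal.metabolic_heat_rate,
                              fetal.maternal_fetal_delta)
    add("heat_conductance_w_kg_c", h, 7.0, 1e-12)
    add("reynolds_uv_inlet",
        phys.reynolds(blood, config.cord.uv_diameter, config.uv_inlet_velocity),
        670.288, 1e-3)
    add("reynolds_ua_inlet",
        phys.reynolds(blood, config.cord.ua_diameter, config.ua_inlet_velocity),
        678.364, 1e-3)
    add("maternal_wall_flux_w_m2",
        phys.wall_heat_flux(h, fetal.fetal_weight, fetal.maternal_fetal_delta,
                            phys.MATERNAL_VESSEL_WALL_AREA),
        11213.6, 1e-3)

    # Poiseuille laws
    add("poiseuille_centerline_over_mean",
        gz.poiseuille_profile(0.0, 1.0, 1.0) / 1.0, 2.0, 1e-12)
    geometry = build_cord_geometry(config.cord, config.points_per_coil)
    bcs = phys.build_boundary_conditions(config.cord, blood, fetal, geometry,
                                         uv_inlet=config.uv_inlet)
    opts = pf.SolverOptions(velocity_mode="mass_conservative")
    uv = pf.solve_vessel(geometry, blood, *bcs["UV"], opts)
    d, L, u = config.cord.uv_diameter, config.cord.cord_length, config.uv_inlet_velocity
    add("uv_hagen_poiseuille_drop_pa", uv.pressure_drop,
        32.0 * blood.dynamic_viscosity * L * u / d**2, 1e-9)

    # exact discrete energy conservation
    thermal = bcs["UA1"][0]
    ua = pf.solve_vessel(geometry, blood, *bcs["UA1"], opts)
    lhs = ua.mass_flow * blood.specific_heat * ua.temperature_change
    rhs = thermal.wall_heat_flux * thermal.wall_area
    add("ua_energy_conservation_w", lhs, rhs, 1e-12)

    # Graetz benchmark: slow flow so the field develops within the tube
    grid = gz.AxisymGrid(n_radial=64, n_axial=256, tube_radius=0.002,
                         tube_length=1.0)
    sol = gz.solve_graetz(grid, blood, mean_velocity=0.01,
                          inlet_temperature=310.0, wall_flux=500.0)
    nu = gz.nusselt_number(sol, 2 * grid.tube_radius)
    add("graetz_developed_nusselt", nu[-1], gz.NU_FULLY_DEVELOPED, 0.01)
    dtb_dz = (sol.bulk_temperature[-1] - sol.bulk_temperature[-2]) / (
        grid.tube_length / grid.n_axial)
    add("graetz_energy_balance_k_m", dtb_dz,
        2 * 500.0 / (blood.density * blood.specific_heat * 0.01
                     * grid.tube_radius), 1e-3)
    return checks
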