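"""Axisymmetric Graetz verification solver.

Steady thermal development of laminar Poiseuille flow in a straight circular
tube with a constant wall heat flux:

    u(r) dT/dz = alpha * (1/r) d/dr ( r dT/dr ),   u(r) = 2U (1 - (r/R)^2),

with zero flux at the axis and prescribed flux q'' at the wall; axial
conduction is neglected (the classical Graetz assumption, valid for Pe >> 1).
This cross-section-resolved solution exists to verify the reduced 1D model:
its bulk temperature must follow the same global energy balance
dT_b/dz = 2 q'' / (rho cp U R), and its fully developed Nusselt number must
approach the analytic 48/11.

Discretization: radial finite volumes on cell centres r_j = (j+1/2) h (the
conservative form keeps the discrete energy balance tight), with a
theta-weighted implicit march in z. Backward Euler (theta = 1) is the default:
the uniform inlet temperature is incompatible with the wall flux, and the
undamped Crank-Nicolson modes excited by that corner discontinuity pollute
the whole profile. In the developed region the axial error vanishes, so the
observed accuracy of the developed Nusselt number is set by the second-order
radial discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .physiology import BloodModel

__all__ = [
    "AxisymGrid",
    "AxisymSolution",
    "BLOOD_THERMAL_CONDUCTIVITY",
    "NU_FULLY_DEVELOPED",
    "poiseuille_profile",
    "solve_graetz",
    "nusselt_number",
]

#: Thermal conductivity of whole blood, W/(m K); configurable in solve_graetz.
BLOOD_THERMAL_CONDUCTIVITY = 0.52
#: Fully developed laminar Nusselt number for constant wall flux.
NU_FULLY_DEVELOPED = 48.0 / 11.0


@dataclass
class AxisymGrid:
    """Grid for the axisymmetric solver: n_radial cells x n_axial steps."""

    n_radial: int
    n_axial: int
    tube_radius: float
    tube_length: float

    def __post_init__(self):
        if self.n_radial < 8:
            raise ValueError("n_radial must be >= 8")
        if self.n_axial < 16:
            raise ValueError("n_axial must be >= 16")
        if self.tube_radius <= 0 or self.tube_length <= 0:
            raise ValueError("tube dimensions must be positive")

    @property
    def r_centers(self) -> np.ndarray:
        h = self.tube_radius / self.n_radial
        return (np.arange(self.n_radial) + 0.5) * h

    @property
    def z_stations(self) -> np.ndarray:
        return np.linspace(0.0, self.tube_length, self.n_axial + 1)


@dataclass
class AxisymSolution:
    """Temperature field T(z, r) plus derived axial profiles."""

    grid: AxisymGrid
    temperature: np.ndarray      # (n_axial + 1, n_radial), K
    bulk_temperature: np.ndarray  # (n_axial + 1,), K
    wall_temperature: np.ndarray  # (n_axial + 1,), K
    wall_flux: float             # W/m^2
    conductivity: float          # W/(m K)
    mean_velocity: float         # m/s


def poiseuille_profile(
    r: float | np.ndarray, mean_velocity: float, tube_radius: float
):
    """Fully developed parabolic profile u(r) = 2U (1 - (r/R)^2).

    The centreline velocity is twice the mean and the wall value is zero
    (no slip).
    """
    r = np.asarray(r, float)
    if np.any(r < 0) or np.any(r > tube_radius):
        raise ValueError("r must lie in [0, tube_radius]")
    out = 2.0 * mean_velocity * (1.0 - (r / tube_radius) ** 2)
    return float(out) if out.ndim == 0 else out


def solve_graetz(
    grid: AxisymGrid,
    blood: BloodModel,
    mean_velocity: float,
    inlet_temperature: float,
    wall_flux: float,
    conductivity: float = BLOOD_THERMAL_CONDUCTIVITY,
    theta: float = 1.0,
) -> AxisymSolution:
    """March the thermal entrance problem down the tube.

    Parameters
    ----------
    mean_velocity:
        Bulk velocity U (m/s); the Poiseuille profile is built from it.
    wall_flux:
        Constant wall heat flux q'' (W/m^2), positive into the fluid.
    theta:
        Implicitness of the axial march (1 = backward Euler, the default;
        0.5 = Crank-Nicolson, which rings off the inlet discontinuity).
    """
    if mean_velocity <= 0:
        raise ValueError("mean_velocity must be positive")
    if conductivity <= 0:
        raise ValueError("conductivity must be positive")
    nr, nz = grid.n_radial, grid.n_axial
    R = grid.tube_radius
    h = R / nr
    dz = grid.tube_length / nz
    alpha = conductivity / (blood.density * blood.specific_heat)

    r_c = grid.r_centers
    r_faces = np.arange(nr + 1) * h
    u = poiseuille_profile(r_c, mean_velocity, R)

    # conservative radial operator: (L T)_j = [r_{j+1/2}(T_{j+1}-T_j)
    #   - r_{j-1/2}(T_j - T_{j-1})] * alpha / (r_j h^2); wall flux enters the
    # last cell as a source, axis face carries zero flux.
    lower = np.zeros(nr)
    diag = np.zeros(nr)
    upper = np.zeros(nr)
    for j in range(nr):
        rw = r_faces[j] if j > 0 else 0.0
        re_ = r_faces[j + 1] if j < nr - 1 else 0.0  # wall face handled as source
        coef = alpha / (r_c[j] * h * h)
        if j > 0:
            lower[j] = coef * rw
        if j < nr - 1:
            upper[j] = coef * re_
        diag[j] = -coef * (rw + re_)
    L = sp.diags(
        [lower[1:], diag, upper[:-1]], offsets=[-1, 0, 1], format="csc"
    )
    src = np.zeros(nr)
    src[-1] = alpha * r_faces[-1] * wall_flux / (conductivity * r_c[-1] * h)

    U_inv = sp.diags(1.0 / u, format="csc")
    A = U_inv @ L           # dT/dz = A T + U_inv src
    b = src / u
    identity = sp.identity(nr, format="csc")
    lhs = (identity - theta * dz * A).tocsc()
    rhs_mat = (identity + (1.0 - theta) * dz * A).tocsc()
    solver = splu(lhs)

    T = np.empty((nz + 1, nr))
    T[0] = inlet_temperature
    for n in range(nz):
        T[n + 1] = solver.solve(rhs_mat @ T[n] + dz * b)

    w = u * r_c  # bulk-averaging weights (midpoint quadrature)
    bulk = (T * w).sum(axis=1) / w.sum()
    # wall temperature: quadratic extrapolation T(r) = a + g(r-R) + c(r-R)^2
    # through the two outermost cell centres, with the slope at the wall
    # pinned to the flux boundary condition g = q''/k.
    g = wall_flux / conductivity
    t1, t2 = T[:, -1], T[:, -2]
    # t1 = a - g h/2 + c h^2/4 and t2 = a - 3 g h/2 + 9 c h^2/4 give:
    c = (g * h - (t1 - t2)) / (2.0 * h * h)
    wall = t1 + g * h / 2.0 - c * h * h / 4.0

    return AxisymSolution(
        grid=grid,
        temperature=T,
        bulk_temperature=bulk,
        wall_temperature=wall,
        wall_flux=wall_flux,
        conductivity=conductivity,
        mean_velocity=mean_velocity,
    )


def nusselt_number(solution: AxisymSolution, tube_diameter: float) -> np.ndarray:
    """Local Nusselt number Nu(z) = q'' D / (k (T_w - T_b)).

    Stations where wall and bulk temperatures coincide (e.g. the adiabatic
    limit or the inlet plane) are returned as NaN rather than raising, so a
    profile with a degenerate leading station is still usable.
    """
    dt = solution.wall_temperature - solution.bulk_temperature
    degenerate = np.abs(dt) < 1e-9 * (np.abs(solution.bulk_temperature) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = solution.wall_flux * tube_diameter / (solution.conductivity * dt)
    nu = np.where(degenerate, np.nan, nu)
    if np.all(np.isnan(nu)):
        raise ValueError("wall and bulk temperatures coincide everywhere")
    return nu
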