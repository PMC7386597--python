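# Methods

## Scope and intent

`cordflow` models the term human umbilical cord as three rigid circular
tubes — a straight vein and two helical arteries — carrying steady, laminar,
incompressible, constant-property blood, exchanging heat with the
intra-amniotic environment through constant wall fluxes. It deliberately
replaces a full 3D conjugate finite-element solve with (a) a reduced-order
per-vessel model whose every term has a closed form to test against, and
(b) exportable surface meshes so that anyone who wants the 3D fields can
feed the same parametric geometry to an external CFD code. Wharton's jelly,
pulsatile flow, compliant walls, shear-thinning rheology and oxygen/nutrient
transport are out of scope.

## Geometry

The cord axis is $x \in [0, L]$ with $x=0$ at the fetal end. The vein is the
segment itself; each artery is the helix

$x = \theta p/2\pi,\quad y = R_h\cos(\pm\theta+\phi),\quad z = R_h\sin(\pm\theta+\phi)$

with pitch $p$, phase $\phi$ ($0$ and $\pi$ for the two arteries) and radius
$R_h = r_{UV} + r_{UA} + c$ fixed by the surface clearance $c$; the sign
encodes handedness (a pure convention, no scalar output depends on it).
Defaults: $L=0.6$ m, $D_{UV}=8.3$ mm, $D_{UA}=4.2$ mm, $p=5$ cm
(12 coils, UCI 0.2 coils/cm), $c=0.2$ mm, hence $R_h = 6.45$ mm and an
arterial arc length of 0.772 m, 29 % longer than the cord.

The coiling index is *measured*, not assumed: full turns are counted from the
unwrapped winding angle of the generated arterial polyline and divided by the
cord length in cm. This makes the metric robust to any future non-uniform
coiling extension and resolution-independent above ~4 points per turn.

Tube surfaces are swept with a double-reflection rotation-minimizing frame
(no spurious twist on helices), triangulated with optional end caps, and
checked for watertightness by edge counting (each undirected edge shared by
exactly two triangles). Sweeps whose tube radius exceeds the local curvature
radius are refused rather than silently self-intersecting; the baseline
artery has a curvature radius of ~16 mm against a 2.1 mm tube radius, far
from that bound. Export formats are binary STL (via trimesh) and legacy
ASCII VTK polydata (written and re-read by the package itself — the format
is a dozen lines of text).

### Wall-area convention

Heat-flux denominators use the lateral area $\pi D L$ with $L$ the *cord*
length ("straight-length" convention), because the baseline flux values
0.0156 m² (UV) and 0.00791 m² (per UA) are built on it. The physically
larger helical-arc area ($\approx$ 0.0102 m² per artery) is available as an
option. Because the temperature solver distributes the total wall power
$q''A_w$ uniformly along whatever arc length it integrates over, energy
conservation is exact under either convention; only the split between flux
and area changes.

## Boundary conditions

The thermal chain, all in °C:

* conductance $H = \dot q_{met} / \Delta T_{mf} = 3.5/0.5 = 7$ W kg⁻¹ °C⁻¹;
* intra-amniotic temperature 37.3 (fetal core 37.5 − 0.2);
* arterial inlet (fetal end) 37.5; venous inlet (placental end) 37.212 from
  the maternal-vessel sub-model (below);
* driving differences $\Delta T_1 = 37.3 - 37.212 = 0.088$ into the vein and
  $\Delta T_2 = 37.3 - 37.5 = -0.2$ out of the arteries;
* wall fluxes $q'' = H \cdot FW \cdot \Delta T / A_w$ with $FW = 3.3$ kg:
  $+129.9$ W/m² (UV) and $-584.1$ W/m² (per UA). (Evaluating the UV
  quotient from its rounded operands gives 130.3–133 depending on rounding;
  the package always computes the formula.)

Flux sign convention: positive heats the lumen, so sign(q″) = sign(ΔT)
always. Mean inlet velocities are the Doppler-derived 61.18 cm/s (UA) and
30.59 cm/s (UV); the vein flows placenta→fetus, the arteries the reverse.
The quoted outlet velocities (35.89 / 17.95 cm/s) are retained only for the
non-conservative emulation mode (below). A 70 mmHg maternal inlet pressure
is carried as metadata; pressure work is negligible at these scales.

### Maternal-vessel sub-model and the specific-heat question

The venous inlet temperature is unobservable, so it is estimated from a
straight tube of placental thickness (0.04 m) carrying maternal blood at
37.0 °C, heated through its wall by the same conductance argument at the
full $\Delta T_{mf}$. The closed-form balance
$T_{out} = T_{in} + H\,FW\,\Delta T_{mf}/(\dot m c_p)$ gives 37.183 °C with
the standard blood $c_p = 3617$ J kg⁻¹ K⁻¹. The baseline instead adopts
37.212 °C — the value this sub-model is reported to produce — which the
balance reproduces only for an effective $c_p \approx 3117$ J kg⁻¹ K⁻¹
(`invert_cp_for_outlet_temperature` performs that inversion). Both routes
are exposed (`uv_inlet="reported" | "maternal_model" | <float>`); the
reported value is the default so the baseline ΔT chain is self-consistent.
The tube diameter is not independently constrained; 8.3 mm is adopted, and
the quoted flux-normalizing area 0.00103 m² (which back-implies ~8.2 mm) is
kept as the constant the 11,213.6 W/m² maternal flux is defined with.

## Reduced per-vessel solver

Uniform finite-volume grid along the vessel arc length (default 600 cells,
≈1 mm on the vein — chosen so the discretization term is invisible next to
the modelling error; the schemes below are exact for the baseline's constant
coefficients anyway). Fields live on the cell faces, so endpoint drops are
exact differences.

* **Velocity.** `mass_conservative` (default): $U$ constant at the inlet
  value, as continuity requires in a rigid constant-area tube. Prescribing
  different inlet and outlet mean velocities in such a tube is inconsistent
  with incompressibility, so the decelerating profiles some reference
  solutions show cannot be conservative; `prescribed_taper` linearly
  interpolates inlet→outlet velocity for qualitative comparison and is
  labelled non-conservative.
* **Pressure.** $dp/ds = -f\,\rho U^2/2D$ integrated upstream from the
  outlet ($p_{out}=0$ reference). $f = 64/\mathrm{Re}$, multiplied for the
  arteries by White's laminar curved-pipe correlation (default; Ito's
  available) in the Dean number $\mathrm{De}=\mathrm{Re}\sqrt{D/2R_h}$,
  ≈387 for the baseline artery, a friction ratio of ≈2.5. Below each
  correlation's validity threshold the multiplier is 1; it is clamped ≥ 1.
  Gravity is off by default (cord orientation is unspecified).
* **Temperature.** Upwind finite volumes for
  $\dot m c_p\,dT/ds = q'$, with $q' = q''A_w/L_{grid}$, making
  $\dot m c_p (T_{out}-T_{in}) = q'' A_w$ an identity of the scheme. When a
  thermal BC carries no area, $A_w = \pi D L_{grid}$ and the profile equals
  the textbook closed form $T_{in} + q''\pi D s/(\dot m c_p)$.
* **Diagnostics.** Wall shear rate $8U/D$; static entropy
  $c_p\ln(T/T_{ref})$, $T_{ref}=298.15$ K by default (a solver-style
  reference state; entropy values shift uniformly with any other choice).

Baseline outcomes with these defaults: UA drop 0.143 K vs UV rise 0.032 K
(ratio 4.44 — independent of $c_p$, since it is a ratio of wall powers over
mass flows), UA pressure drop ≈8.5 kPa vs UV ≈341 Pa (Hagen–Poiseuille
closed form). Reference 3D endpoint values (e.g. a 0.265 °C arterial drop or
16.9 kPa arterial pressure drop) depend on the non-conservative outlet
velocities and an unstated specific heat and are treated as qualitative
context, not targets; likewise a venous *cooling* despite an inward wall
flux cannot satisfy an energy balance and is not reproduced.

## Graetz verification solver

The axisymmetric advection–diffusion equation with Poiseuille advection and
Neumann wall flux is discretized with radial finite volumes on cell centres
(conservative: the discrete bulk temperature obeys the wall-power balance to
round-off per step) and a theta-weighted implicit axial march. Backward
Euler ($\theta=1$) is the default: the uniform inlet temperature is
incompatible with the wall flux at the corner, and Crank–Nicolson's
undamped modes ring visibly in the Nusselt profile. In the developed region
the axial error vanishes, so accuracy is governed by the second-order radial
stencil: at 64×256 the developed Nusselt is 4.3638 vs the analytic
48/11 = 4.3636 (0.005 %), and halving both spacings cuts the error ~4×.
Wall temperature is recovered by quadratic extrapolation pinned to the
flux gradient. Thermal conductivity defaults to 0.52 W m⁻¹ K⁻¹ (whole
blood); it affects only this verification solver, never the reduced model's
energy balance. Axial conduction is neglected (Pe ≫ 1 everywhere used).

The verification benchmark runs at $R=2$ mm, $L=1$ m, $U=1$ cm/s: blood's
Prandtl number (≈28) makes the baseline cord *thermally developing* over
several metres, so a slower flow is needed for the developed-Nu check to be
meaningful within a tube of sensible length. That choice is a property of
the benchmark, not of the cord model.

## Configuration, reporting, determinism

`RunConfig` (pydantic) defaults to the baseline scenario; YAML/JSON files
round-trip exactly and accept unit-suffixed strings ("8.3 mm",
"61.18 cm/s", "310.65 K"). `run_scenario` is fully deterministic — two runs
produce byte-identical JSON summaries. Profile CSVs map each vessel's arc
coordinate to the cord axis (0 = fetal end), so venous profiles read
right-to-left in cord coordinates. The grid-convergence statistic is the
symmetric percent difference $|a-b|/\overline{ab}\cdot 100$; of the quoted
sparse/dense velocity rows it reproduces 2.179 % and 3.051 % exactly, while
the "vein output" row (4.354) is not reproducible from its printed operands
under any simple convention and is excluded from tests.

## What the tests do and do not show

The suite pins: the analytic geometry identities and their discretizations;
the full boundary-condition arithmetic chain; exact discrete energy
conservation; closed-form pressure/temperature profiles; curved-pipe
friction bounds and limits; the Graetz solver against 48/11 and the exact
bulk balance; and determinism/round-trip of all I/O. It does not — cannot —
validate the model against in-vivo cords: real cords have pulsatile flow,
compliant walls, non-uniform coiling, perfused Wharton's jelly and
measurement scatter in every input. Passing tests certify internal
consistency and agreement with classical pipe-flow theory under the stated
idealizations, and those idealizations are listed above precisely so users
can judge their distance from any particular clinical question.

## Known limitations

* Single-phase, Newtonian, constant-property blood; no shear-thinning index.
* Steady flow only; arterial pulsatility is averaged away.
* The 0.2 mm inter-vessel gap is geometric only; no conduction through it.
* The two arteries are identical up to phase; no anastomosis at the
  placental end.
* Secondary (Dean-vortex) velocity structure enters only through the
  friction correlation, not as a resolved field.
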