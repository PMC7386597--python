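"""Derive the physiological boundary conditions for the baseline scenario.

A term fetus produces ~3.5 W/kg of metabolic heat while sitting 0.5 degC
above the maternal core, which fixes the fetal-maternal heat conductance at
7 W/(kg degC). That conductance, the 3.3 kg fetal weight, and the per-vessel
temperature differences against the intra-amniotic space (37.3 degC) turn
into constant wall heat fluxes over each vessel's lateral area.
"""

import cordflow as cf

blood, fetal = cf.BloodModel(), cf.FetalParams()
spec = cf.CordSpec()
geom = cf.build_cord_geometry(spec)

h = cf.heat_conductance(fetal.metabolic_heat_rate, fetal.maternal_fetal_delta)
print(f"heat conductance       : {h:.1f} W/(kg degC)")

re_uv = cf.reynolds(blood, spec.uv_diameter, 0.3059)
re_ua = cf.reynolds(blood, spec.ua_diameter, 0.6118)
print(f"Reynolds numbers       : UV {re_uv:.3f}, UA {re_ua:.3f} "
      f"(laminar: {cf.is_laminar(re_uv) and cf.is_laminar(re_ua)})")

t_out = cf.maternal_vessel_outlet_temperature(blood, fetal)
cp_eff = cf.invert_cp_for_outlet_temperature(blood, fetal, 37.212)
print(f"maternal-vessel outlet : {t_out:.3f} degC at cp = {blood.specific_heat}")
print(f"  (the adopted 37.212 degC corresponds to cp = {cp_eff:.0f} J/kg/K)")

bcs = cf.build_boundary_conditions(spec, blood, fetal, geom)
for vid, (thermal, flow) in bcs.items():
    print(f"{vid}: q'' = {thermal.wall_heat_flux:+8.1f} W/m^2 "
          f"(dT = {thermal.delta_T:+.3f} degC), inlet "
          f"{thermal.inlet_temperature:.3f} K, "
          f"U = {flow.inlet_mean_velocity} m/s, {flow.flow_direction}")

# Positive flux warms the lumen: the amniotic space feeds a little heat into
# the cooler venous blood, while the warmer arterial blood sheds heat out.
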