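"""Sweep the coil pitch: how coiling intensity shapes transport.

Tighter coiling (higher umbilical coiling index) lengthens the arterial path
and raises the Dean number, so the arterial pressure drop grows while the
venous one is untouched. Clinically, hyper- and hypocoiled cords sit at the
ends of this sweep.
"""

import cordflow as cf

table = cf.sweep_scenarios(
    cf.RunConfig(),
    {"cord.coil_pitch": [0.1, 0.05, 0.025]},  # UCI 0.1, 0.2, 0.4 coils/cm
)
cols = ["cord.coil_pitch", "uci_coils_per_cm", "UA1_pressure_drop_pa",
        "UA1_temperature_change_k", "UV_pressure_drop_pa"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nArterial pressure drop rises steeply with coiling; the straight "
      "vein is indifferent to pitch.")
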