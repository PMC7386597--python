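"""Small unit-coercion helpers for configuration input.

All internal computation is SI (m, m/s, Pa, K, kg, W). Configuration files may
give values either as bare numbers (interpreted as SI) or as strings with an
explicit unit suffix, e.g. ``"8.3 mm"``, ``"61.18 cm/s"``, ``"70 mmHg"``,
``"37.5 C"``. Temperatures given in Celsius are converted to Kelvin only where
a field is declared in Kelvin; physiological set-points are kept in Celsius
because that is how they are specified clinically.
"""

from __future__ import annotations

CELSIUS_OFFSET = 273.15
MMHG_TO_PA = 133.322387415

_LENGTH = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6}
_VELOCITY = {"m/s": 1.0, "cm/s": 1e-2, "mm/s": 1e-3}
_PRESSURE = {"pa": 1.0, "kpa": 1e3, "mmhg": MMHG_TO_PA}


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


def _split(value: str) -> tuple[float, str]:
    parts = value.strip().split()
    if len(parts) == 2:
        return float(parts[0]), parts[1]
    # allow "8.3mm" style
    s = value.strip()
    i = len(s)
    while i > 0 and not (s[i - 1].isdigit() or s[i - 1] == "."):
        i -= 1
    if i == 0 or i == len(s):
        raise ValueError(f"cannot parse quantity {value!r}")
    return float(s[:i]), s[i:]


def parse_length(value: float | str) -> float:
    """Return a length in metres from a number (m) or suffixed string."""
    if isinstance(value, str):
        mag, unit = _split(value)
        try:
            return mag * _LENGTH[unit.lower()]
        except KeyError:
            raise ValueError(f"unknown length unit {unit!r}") from None
    return float(value)


def parse_velocity(value: float | str) -> float:
    """Return a velocity in m/s from a number (m/s) or suffixed string."""
    if isinstance(value, str):
        mag, unit = _split(value)
        try:
            return mag * _VELOCITY[unit.lower()]
        except KeyError:
            raise ValueError(f"unknown velocity unit {unit!r}") from None
    return float(value)


def parse_pressure(value: float | str) -> float:
    """Return a pressure in Pa from a number (Pa) or suffixed string."""
    if isinstance(value, str):
        mag, unit = _split(value)
        try:
            return mag * _PRESSURE[unit.lower()]
        except KeyError:
            raise ValueError(f"unknown pressure unit {unit!r}") from None
    return float(value)


def parse_temperature_celsius(value: float | str) -> float:
    """Return a temperature in degrees Celsius.

    Bare numbers are taken as Celsius; strings may be suffixed ``C``/``degC``
    or ``K`` (converted).
    """
    if isinstance(value, str):
        mag, unit = _split(value)
        u = unit.lower().lstrip("°")
        if u in ("c", "degc", "celsius"):
            return mag
        if u in ("k", "kelvin"):
            return kelvin_to_celsius(mag)
        raise ValueError(f"unknown temperature unit {unit!r}")
    return float(value)
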