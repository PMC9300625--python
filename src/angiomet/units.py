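"""Unit handling.

All internal computations use a single unit system:

* length: micrometre (um)
* time: hour (h)
* concentration: millimole per litre (mmol/l)
* pressure: pascal (Pa)

Derived internal units follow (diffusivity um^2/h, permeability um/h,
viscosity Pa*h, volumetric uptake mmol/(l*h), ...).  Configuration files may
state any quantity as a ``"<value> <unit>"`` string in one of the accepted
external units below; bare numbers are taken to be already in the internal
unit.  Conversion happens once, at load time.
"""

from __future__ import annotations

from .errors import ConfigError

_H_PER_S = 1.0 / 3600.0

#: factor table: kind -> unit -> multiplier into the internal unit
FACTORS: dict[str, dict[str, float]] = {
    "length": {"um": 1.0, "mm": 1e3, "cm": 1e4, "m": 1e6, "nm": 1e-3},
    "time": {"h": 1.0, "s": _H_PER_S, "min": 1.0 / 60.0, "d": 24.0},
    "rate": {"1/h": 1.0, "1/s": 3600.0, "1/min": 60.0},
    "concentration": {
        "mmol/l": 1.0, "mM": 1.0, "mol/l": 1e3, "M": 1e3,
        "umol/l": 1e-3, "uM": 1e-3,
    },
    "conc_rate": {
        "mmol/(l*h)": 1.0, "mmol/(l*min)": 60.0, "mmol/(l*s)": 3600.0,
        "mol/(l*h)": 1e3,
    },
    "diffusivity": {
        "um^2/h": 1.0, "um^2/s": 3600.0,
        "cm^2/s": 1e8 * 3600.0, "m^2/s": 1e12 * 3600.0,
    },
    "speed": {
        "um/h": 1.0, "um/s": 3600.0, "cm/s": 1e4 * 3600.0,
        "mm/h": 1e3, "m/s": 1e6 * 3600.0,
    },
    "pressure": {"Pa": 1.0, "kPa": 1e3, "mmHg": 133.322},
    "viscosity": {"Pa*h": 1.0, "Pa*s": _H_PER_S, "mPa*s": 1e-3 * _H_PER_S, "cP": 1e-3 * _H_PER_S},
    "shear": {"Pa": 1.0, "dyn/cm^2": 0.1},
    "flow": {"um^3/h": 1.0, "um^3/s": 3600.0},
    "dimensionless": {"": 1.0, "1": 1.0},
    "sites_rate": {"sites/h": 1.0, "sites/min": 60.0},
}


def _normalize(unit: str) -> str:
    return (
        unit.strip()
        .replace("µ", "u")   # micro sign
        .replace("μ", "u")   # greek mu
        .replace("·", "*")
        .replace(" ", "")
        .replace("**", "^")
        .replace("²", "^2")
        .replace("³", "^3")
    )


def convert(value: float, unit: str, kind: str) -> float:
    """Convert ``value`` expressed in ``unit`` into the internal unit for ``kind``."""
    table = FACTORS.get(kind)
    if table is None:
        raise ConfigError([f"unknown quantity kind '{kind}'"])
    norm = {_normalize(u): f for u, f in table.items()}
    key = _normalize(unit)
    if key not in norm:
        raise ConfigError(
            [f"unit '{unit}' is not valid for kind '{kind}' "
             f"(accepted: {', '.join(sorted(table))})"]
        )
    return float(value) * norm[key]


def parse_quantity(raw, kind: str, path: str = "?") -> float:
    """Parse a config quantity.

    ``raw`` may be a number (already internal units) or a string
    ``"<number> <unit>"``; returns the value in internal units.
    """
    if isinstance(raw, bool):
        raise ConfigError([f"{path}: expected a quantity, got a boolean"])
    if isinstance(raw, (int, float)):
        return float(raw)
    if isinstance(raw, str):
        parts = raw.strip().split(None, 1)
        if not parts:
            raise ConfigError([f"{path}: empty quantity string"])
        try:
            value = float(parts[0])
        except ValueError:
            raise ConfigError([f"{path}: cannot parse number from '{raw}'"]) from None
        unit = parts[1] if len(parts) == 2 else ""
        try:
            return convert(value, unit, kind)
        except ConfigError as exc:
            raise ConfigError([f"{path}: {p}" for p in exc.problems]) from None
    raise ConfigError([f"{path}: expected number or '<value> <unit>' string, got {type(raw).__name__}"])
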