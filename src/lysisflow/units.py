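"""Unit conversion for the clinical/bench interface layer.

Internally the package computes strictly in SI (m, s, Pa, m^3/s, mol/m^3).
The interface layer accepts and emits the units practitioners use at the
bench: mmHg for pressures, L/min for flows, inches for tubing bores,
minutes for fluorometer time, micromolar for reagent concentrations.

Conversion constants are exact where a legal definition exists:
1 in = 25.4 mm and 1 mmHg = 133.322 Pa (conventional millimetre of mercury
to the precision used throughout).
"""

from __future__ import annotations

from .errors import ConversionError

MMHG_PA: float = 133.322
"""Pascals per millimetre of mercury."""

INCH_M: float = 0.0254
"""Metres per inch (exact)."""

STANDARD_GRAVITY: float = 9.80665
"""Standard acceleration of gravity, m/s^2 (exact by definition)."""

# unit -> (dimension, factor to the SI unit of that dimension)
_UNIT_TABLE: dict[str, tuple[str, float]] = {
    # pressure -> Pa
    "Pa": ("pressure", 1.0),
    "kPa": ("pressure", 1e3),
    "mmHg": ("pressure", MMHG_PA),
    # length -> m
    "m": ("length", 1.0),
    "cm": ("length", 1e-2),
    "mm": ("length", 1e-3),
    "um": ("length", 1e-6),
    "µm": ("length", 1e-6),
    "in": ("length", INCH_M),
    # volumetric flow -> m^3/s
    "m3/s": ("flow", 1.0),
    "L/min": ("flow", 1e-3 / 60.0),
    "mL/min": ("flow", 1e-6 / 60.0),
    "uL/h": ("flow", 1e-9 / 3600.0),
    # volume -> m^3
    "m3": ("volume", 1.0),
    "L": ("volume", 1e-3),
    "mL": ("volume", 1e-6),
    "cc": ("volume", 1e-6),
    "uL": ("volume", 1e-9),
    # time -> s
    "s": ("time", 1.0),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    # frequency / rate -> Hz (= 1/s)
    "Hz": ("frequency", 1.0),
    "1/min": ("frequency", 1.0 / 60.0),
    "RPM": ("frequency", 1.0 / 60.0),
    "1/s": ("frequency", 1.0),
    # molar concentration -> mol/m^3
    "mol/m3": ("concentration", 1.0),
    "M": ("concentration", 1e3),
    "mM": ("concentration", 1.0),
    "uM": ("concentration", 1e-3),
    "µM": ("concentration", 1e-3),
    "nM": ("concentration", 1e-6),
    # mass concentration -> kg/m^3
    "kg/m3": ("mass_concentration", 1.0),
    "mg/mL": ("mass_concentration", 1.0),
    "g/L": ("mass_concentration", 1.0),
    # viscosity
    "Pa.s": ("dynamic_viscosity", 1.0),
    "cP": ("dynamic_viscosity", 1e-3),
    "m2/s": ("kinematic_viscosity", 1.0),
    "cSt": ("kinematic_viscosity", 1e-6),
    # density
    "kg/m^3": ("density", 1.0),
    # shear rate
    "s-1": ("shear_rate", 1.0),
}

# aliases normalised before lookup
_ALIASES = {
    "m^3/s": "m3/s",
    "m^3": "m3",
    "mol/m^3": "mol/m3",
    "l/min": "L/min",
    "ml": "mL",
    "ml/min": "mL/min",
    "pa": "Pa",
    "mmhg": "mmHg",
    "rpm": "RPM",
    "1/s": "1/s",
    "/s": "s-1",
    "Pa*s": "Pa.s",
}


def _lookup(unit: str) -> tuple[str, float]:
    key = _ALIASES.get(unit, unit)
    if key not in _UNIT_TABLE:
        key = _ALIASES.get(unit.strip(), unit.strip())
    try:
        return _UNIT_TABLE[key]
    except KeyError:
        raise ConversionError(
            f"unknown unit {unit!r}; supported: {sorted(_UNIT_TABLE)}"
        ) from None


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension.

    Raises :class:`~lysisflow.errors.ConversionError` for unknown units or
    dimensionally incompatible pairs.
    """
    dim_from, f_from = _lookup(from_unit)
    dim_to, f_to = _lookup(to_unit)
    if dim_from != dim_to:
        # density / mass-concentration are numerically the same dimension
        compatible = {dim_from, dim_to} <= {"density", "mass_concentration"} or {
            dim_from,
            dim_to,
        } <= {"frequency", "shear_rate"}
        if not compatible:
            raise ConversionError(
                f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
            )
    return value * f_from / f_to


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_PA
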