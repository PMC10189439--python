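"""Unit-tagged device configuration.

Every dimensioned scalar in the YAML/JSON config is a string of the
form ``"<number> <unit>"`` (``"5.2 L/min"``, ``"5/32 in"``); bare
numbers are rejected for dimensioned fields so a silently wrong unit
cannot enter the pipeline.  Fractions like ``5/32`` are accepted in the
numeric part because tubing bores are quoted that way.  Parsed values
are converted to SI immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml

from .errors import ConfigError
from .loop_simulator import DampenerSpec, DEFAULT_REFERENCE_PRESSURE
from .scaling_design import ConduitSpec, FluidSpec, PumpLaw, TargetVessel
from .units import convert_units

__all__ = ["DeviceConfig", "parse_quantity", "load_config", "default_config"]

_SI_UNIT = {
    "length": "m",
    "pressure": "Pa",
    "flow": "m3/s",
    "volume": "m3",
    "time": "s",
    "frequency": "Hz",
    "concentration": "mol/m3",
    "kinematic_viscosity": "m2/s",
    "dynamic_viscosity": "Pa.s",
    "density": "kg/m3",
    "shear_rate": "s-1",
}


def parse_quantity(raw, dimension: str, field_name: str = "") -> float:
    """Parse ``"<number> <unit>"`` into SI units of ``dimension``."""
    if not isinstance(raw, str):
        raise ConfigError(
            f"field {field_name or dimension!r} must be a unit-tagged string "
            f'like "3.97 mm", got {raw!r}'
        )
    parts = raw.strip().split(maxsplit=1)
    if len(parts) != 2:
        raise ConfigError(f"field {field_name or dimension!r}: missing unit in {raw!r}")
    num, unit = parts
    try:
        value = float(Fraction(num)) if "/" in num else float(num)
    except ValueError:
        raise ConfigError(f"field {field_name}: bad number {num!r}") from None
    return convert_units(value, unit, _SI_UNIT[dimension])


@dataclass(frozen=True)
class DeviceConfig:
    """Full bench description: fluids, tubing, pump, dampener, target vessel."""

    model_fluid: FluidSpec
    target: TargetVessel
    pump: PumpLaw
    dampener: DampenerSpec
    upstream_segment: ConduitSpec
    downstream_segment: ConduitSpec
    drum_radius: float  # m (Chandler loop)
    tubing_id: float  # m
    clot_resistance_factor: float = 2.0
    reservoir_pressure: float = 12.0 * 133.322  # Pa
    seed: int = 0
    preset_overrides: dict = field(default_factory=dict)


def _fluid(node: dict, name: str) -> FluidSpec:
    return FluidSpec(
        density=parse_quantity(node["density"], "density", f"{name}.density"),
        kinematic_viscosity=parse_quantity(
            node["kinematic_viscosity"], "kinematic_viscosity",
            f"{name}.kinematic_viscosity",
        ),
    )


def load_config(path: str | Path) -> DeviceConfig:
    """Load and validate a YAML/JSON device configuration."""
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_from_dict(raw: dict) -> DeviceConfig:
    """Build a :class:`DeviceConfig` from an already-parsed mapping."""
    try:
        model_fluid = _fluid(raw["model_fluid"], "model_fluid")
        tv = raw["target_vessel"]
        target = TargetVessel(
            diameter=parse_quantity(tv["diameter"], "length", "target_vessel.diameter"),
            mean_flow=parse_quantity(tv["mean_flow"], "flow", "target_vessel.mean_flow"),
            pulse_frequency=parse_quantity(
                tv["pulse_frequency"], "frequency", "target_vessel.pulse_frequency"
            ),
            mean_pressure=parse_quantity(
                tv["mean_pressure"], "pressure", "target_vessel.mean_pressure"
            ),
            fluid=_fluid(tv["fluid"], "target_vessel.fluid"),
        )
        pm = raw["pump"]
        pump = PumpLaw(
            volume_per_cycle=parse_quantity(
                pm["volume_per_cycle"], "volume", "pump.volume_per_cycle"
            ),
            rollers=int(pm.get("rollers", 3)),
            empirical_shear_per_rpm=pm.get("empirical_shear_per_rpm"),
        )
        dm = raw["dampener"]
        dampener = DampenerSpec(
            syringe_capacity=parse_quantity(
                dm["syringe_capacity"], "volume", "dampener.syringe_capacity"
            ),
            air_volume=parse_quantity(dm["air_volume"], "volume", "dampener.air_volume"),
            reference_pressure=(
                parse_quantity(
                    dm["reference_pressure"], "pressure", "dampener.reference_pressure"
                )
                if "reference_pressure" in dm
                else DEFAULT_REFERENCE_PRESSURE
            ),
        )
        tubing_id = parse_quantity(raw["tubing"]["inner_diameter"], "length",
                                   "tubing.inner_diameter")
        upstream = ConduitSpec(
            diameter=tubing_id,
            length=parse_quantity(raw["tubing"]["upstream_length"], "length",
                                  "tubing.upstream_length"),
        )
        downstream = ConduitSpec(
            diameter=tubing_id,
            length=parse_quantity(raw["tubing"]["downstream_length"], "length",
                                  "tubing.downstream_length"),
        )
        return DeviceConfig(
            model_fluid=model_fluid,
            target=target,
            pump=pump,
            dampener=dampener,
            upstream_segment=upstream,
            downstream_segment=downstream,
            drum_radius=parse_quantity(raw["drum_radius"], "length", "drum_radius"),
            tubing_id=tubing_id,
            clot_resistance_factor=float(raw.get("clot_resistance_factor", 2.0)),
            reservoir_pressure=(
                parse_quantity(raw["reservoir_pressure"], "pressure", "reservoir_pressure")
                if "reservoir_pressure" in raw
                else 12.0 * 133.322
            ),
            seed=int(raw.get("seed", 0)),
            preset_overrides=raw.get("preset_overrides", {}),
        )
    except KeyError as exc:
        raise ConfigError(f"missing config key: {exc}") from exc


DEFAULT_CONFIG_YAML = """\
# Bench flow-loop configuration.  Every dimensioned field is a
# unit-tagged string; bare numbers are rejected.
model_fluid:           # pooled plasma at 37 C
  density: "1025 kg/m3"
  kinematic_viscosity: "1.268e-6 m2/s"
target_vessel:         # human main pulmonary artery
  diameter: "27 mm"
  mean_flow: "5.2 L/min"
  pulse_frequency: "1.2 Hz"
  mean_pressure: "12 mmHg"
  fluid:
    density: "1060 kg/m3"
    kinematic_viscosity: "3.3e-6 m2/s"
pump:
  volume_per_cycle: "25 mL"   # from Qbar = 1 L/min x f/40 (f in cycles/min)
  rollers: 3
  empirical_shear_per_rpm: 4.8824  # 913 s^-1 at 187 RPM
dampener:
  syringe_capacity: "60 mL"
  air_volume: "60 mL"
  reference_pressure: "772 mmHg"
tubing:
  inner_diameter: "5/32 in"
  upstream_length: "36 cm"
  downstream_length: "20 cm"
drum_radius: "5.5 cm"
clot_resistance_factor: 2.0
reservoir_pressure: "12 mmHg"
seed: 0
"""


def default_config() -> DeviceConfig:
    """The stock bench configuration (also available as YAML text)."""
    return config_from_dict(yaml.safe_load(DEFAULT_CONFIG_YAML))
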