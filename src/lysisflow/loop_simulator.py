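"""Lumped-parameter simulation of the bench flow loop.

The loop is modelled as a minimal two-node resistance-compliance (RC)
network, the hydraulic analogue of a Windkessel:

* the peristaltic pump is an ideal flow source Q_pump(t);
* the air column trapped in the syringe dampener is an isothermal gas
  compliance C = V_a / P_ref attached at the pump outlet node P1
  (Boyle's law linearised about the absolute reference pressure P_ref);
* tubing segments are Hagen-Poiseuille resistances; the clot multiplies
  the resistance between the two pressure sensors;
* the elevated reservoir is a constant-pressure sink P_res.

State equation (single ODE, integrated with fixed-step RK4):

    C dP1/dt = Q_pump(t) - (P1 - P_res) / R_total

with R_total = R_up + factor * R_down.  Sensor A sits after the upstream
segment and before the clot, sensor B between the clot and the
downstream return line:

    Q_out = (P1 - P_res) / R_total
    P_A   = P1   - R_up  * Q_out
    P_B   = P_res + R_down * Q_out

Large air volumes make C large, so the RC corner frequency
1/(2 pi R C) drops below the peristalsis frequency and pulsation is
filtered out; small air volumes pass it through.  This reproduces the
observed dampener behaviour (pressure amplitude rising as the air
volume shrinks) qualitatively; quantitative amplitudes depend on tubing
details not modelled here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import (
    InsufficientDataError,
    IntegrationError,
    InvalidGeometryError,
)
from .scaling_design import ConduitSpec, FluidSpec, poiseuille_resistance
from .units import MMHG_PA

__all__ = [
    "DampenerSpec",
    "PumpWaveform",
    "LoopLayout",
    "PressureTrace",
    "WaveformSummary",
    "pump_flow_waveform",
    "simulate_loop",
    "summarize_waveform",
    "heartbeat_gate",
]

#: Default absolute reference pressure: atmosphere + 12 mmHg operating mean.
DEFAULT_REFERENCE_PRESSURE = 772.0 * MMHG_PA

Shape = Literal["rectified_sine", "constant", "gated", "sine"]


@dataclass(frozen=True)
class DampenerSpec:
    """Air-filled syringe compliance.

    ``air_volume`` is the trapped air column V_a (m^3) once the plunger
    has self-balanced; ``reference_pressure`` is the absolute pressure
    (Pa) about which the gas compliance C = V_a/P_ref is linearised.
    """

    syringe_capacity: float  # m^3
    air_volume: float  # m^3
    reference_pressure: float = DEFAULT_REFERENCE_PRESSURE  # Pa absolute

    def __post_init__(self) -> None:
        if not 0 < self.air_volume <= self.syringe_capacity:
            raise InvalidGeometryError(
                "air_volume must satisfy 0 < V_a <= syringe_capacity"
            )
        if self.reference_pressure <= 0:
            raise InvalidGeometryError("reference_pressure must be positive (absolute)")

    @property
    def compliance(self) -> float:
        """Isothermal gas compliance dV/dP = V_a / P_ref, m^3/Pa."""
        return self.air_volume / self.reference_pressure


@dataclass(frozen=True)
class PumpWaveform:
    """Instantaneous flow program of the pump.

    Shapes: ``rectified_sine`` (peristaltic rollers), ``constant``,
    ``gated`` (on/off heartbeat bot; on-amplitude 1/duty preserves the
    mean), and ``sine`` (small-signal test input
    Q(t) = Qbar (1 + m sin 2 pi f t), modulation depth ``modulation``).
    All shapes time-average to ``mean_flow`` over whole periods.
    """

    mean_flow: float  # m^3/s
    pulse_frequency: float  # Hz
    shape: Shape = "rectified_sine"
    duty: float = 1.0
    modulation: float = 0.1

    def __post_init__(self) -> None:
        if self.mean_flow < 0:
            raise InvalidGeometryError("mean_flow must be >= 0")
        if self.shape != "constant" and self.pulse_frequency <= 0:
            raise InvalidGeometryError("pulse_frequency must be positive")
        if not 0 < self.duty <= 1:
            raise InvalidGeometryError("duty must be in (0, 1]")
        if not 0 <= self.modulation < 1:
            raise InvalidGeometryError("modulation must be in [0, 1)")


@dataclass(frozen=True)
class LoopLayout:
    """Tubing topology between pump node and reservoir."""

    upstream_segment: ConduitSpec  # pump/dampener node -> sensor A
    downstream_segment: ConduitSpec  # sensor B -> reservoir
    fluid: FluidSpec
    clot_resistance_factor: float = 1.0  # multiplier on downstream resistance
    reservoir_pressure: float = 12.0 * MMHG_PA  # Pa gauge

    def __post_init__(self) -> None:
        if self.clot_resistance_factor < 1:
            raise InvalidGeometryError("clot_resistance_factor must be >= 1")

    @property
    def upstream_resistance(self) -> float:
        return poiseuille_resistance(self.upstream_segment, self.fluid)

    @property
    def downstream_resistance(self) -> float:
        return poiseuille_resistance(self.downstream_segment, self.fluid)

    @property
    def total_resistance(self) -> float:
        return (
            self.upstream_resistance
            + self.clot_resistance_factor * self.downstream_resistance
        )


@dataclass(frozen=True)
class PressureTrace:
    """Simulated or measured pressures at sensors A and B."""

    time: np.ndarray  # s, strictly increasing
    pressure_a: np.ndarray  # Pa
    pressure_b: np.ndarray  # Pa

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        pa = np.asarray(self.pressure_a, dtype=float)
        pb = np.asarray(self.pressure_b, dtype=float)
        if not (len(t) == len(pa) == len(pb)):
            raise InvalidGeometryError("time/pressure arrays must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidGeometryError("time must be strictly increasing")
        if not (np.all(np.isfinite(pa)) and np.all(np.isfinite(pb))):
            raise InvalidGeometryError("pressures must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure_a", pa)
        object.__setattr__(self, "pressure_b", pb)


@dataclass(frozen=True)
class WaveformSummary:
    """Systolic/diastolic summary of a periodic pressure signal."""

    systolic: float  # Pa, mean of per-cycle maxima
    diastolic: float  # Pa, mean of per-cycle minima
    amplitude: float  # Pa, systolic - diastolic
    mean: float  # Pa, time average
    period: float  # s; nan for a constant trace


def pump_flow_waveform(t: np.ndarray | float, pump: PumpWaveform) -> np.ndarray | float:
    """Instantaneous pump flow Q(t), m^3/s (vectorised over t)."""
    t = np.asarray(t, dtype=float)
    q = pump.mean_flow
    f = pump.pulse_frequency
    if pump.shape == "constant":
        out = np.full_like(t, q)
    elif pump.shape == "rectified_sine":
        out = q * (math.pi / 2.0) * np.abs(np.sin(math.pi * f * t))
    elif pump.shape == "gated":
        phase = np.mod(t * f, 1.0)
        out = np.where(phase < pump.duty, q / pump.duty, 0.0)
    elif pump.shape == "sine":
        out = q * (1.0 + pump.modulation * np.sin(2.0 * math.pi * f * t))
    else:  # pragma: no cover - dataclass validation forbids this
        raise InvalidGeometryError(f"unknown shape {pump.shape!r}")
    return out if out.ndim else float(out)


def heartbeat_gate(
    pump: PumpWaveform, gate_frequency: float, duty: float
) -> PumpWaveform:
    """Gate a pump program on/off at heartbeat rate, preserving mean flow.

    Emulates the finger-bot that toggles the pump at ~1 Hz: within each
    gate period the pump runs at ``mean_flow/duty`` for ``duty`` of the
    period and is off otherwise, so the delivered volume per period is
    unchanged.
    """
    if not 0 < duty < 1:
        raise InvalidGeometryError(f"duty must be in (0, 1), got {duty}")
    if gate_frequency <= 0:
        raise InvalidGeometryError("gate_frequency must be positive")
    return PumpWaveform(
        mean_flow=pump.mean_flow,
        pulse_frequency=gate_frequency,
        shape="gated",
        duty=duty,
    )


def simulate_loop(
    layout: LoopLayout,
    pump: PumpWaveform,
    dampener: DampenerSpec,
    duration: float,
    dt: float,
) -> PressureTrace:
    """Integrate the loop ODE and return the post-transient pressure trace.

    ``duration`` should cover at least ~20 pulse periods; ``dt`` must
    resolve the pulsation (dt <= 1/(200 f)).  The first half of the
    simulation is discarded as start-up transient.
    """
    f = pump.pulse_frequency if pump.shape != "constant" else 1.0
    if dt <= 0:
        raise InvalidGeometryError("dt must be positive")
    if pump.shape != "constant" and dt > 1.0 / (200.0 * f):
        raise InvalidGeometryError(
            f"dt={dt} too coarse for f={f} Hz; need dt <= {1.0 / (200.0 * f):.3g}"
        )
    c = dampener.compliance
    r_up = layout.upstream_resistance
    r_down = layout.downstream_resistance
    r_total = layout.total_resistance
    p_res = layout.reservoir_pressure

    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt

    def rhs(ti: float, p1: float) -> float:
        qp = pump_flow_waveform(ti, pump)
        return (qp - (p1 - p_res) / r_total) / c

    p1 = np.empty(n)
    # start at the steady operating point to shorten the transient
    p1[0] = p_res + r_total * pump.mean_flow
    for i in range(n - 1):
        ti, yi = t[i], p1[i]
        k1 = rhs(ti, yi)
        k2 = rhs(ti + dt / 2.0, yi + dt / 2.0 * k1)
        k3 = rhs(ti + dt / 2.0, yi + dt / 2.0 * k2)
        k4 = rhs(ti + dt, yi + dt * k3)
        p1[i + 1] = yi + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(p1[i + 1]):
            raise IntegrationError(
                f"loop integration diverged at t={t[i + 1]:.4g} s with dt={dt}; "
                "reduce dt"
            )

    q_out = (p1 - p_res) / r_total
    pa = p1 - r_up * q_out
    pb = p_res + r_down * q_out
    keep = t >= duration / 2.0
    return PressureTrace(time=t[keep], pressure_a=pa[keep], pressure_b=pb[keep])


def _cycle_extrema(t: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    """Per-cycle systolic/diastolic means and period via zero crossings."""
    x = p - p.mean()
    sign = np.signbit(x)
    rising = np.nonzero(~sign[1:] & sign[:-1])[0] + 1
    if len(rising) < 4:
        raise InsufficientDataError(
            "trace spans fewer than 3 full periods post-transient"
        )
    maxima, minima = [], []
    for a, b in zip(rising[:-1], rising[1:]):
        seg = p[a:b]
        maxima.append(seg.max())
        minima.append(seg.min())
    period = float(np.mean(np.diff(t[rising])))
    return float(np.mean(maxima)), float(np.mean(minima)), period


def summarize_waveform(trace: PressureTrace, sensor: str = "B") -> WaveformSummary:
    """Systolic/diastolic/amplitude/mean/period of one sensor channel.

    Systolic and diastolic are the means of per-cycle maxima and minima;
    cycles are delimited by rising zero crossings of the mean-detrended
    signal.  A constant trace summarises to zero amplitude and undefined
    (nan) period.
    """
    key = sensor.upper()
    if key not in {"A", "B"}:
        raise InvalidGeometryError(f"sensor must be 'A' or 'B', got {sensor!r}")
    p = trace.pressure_a if key == "A" else trace.pressure_b
    t = trace.time
    if len(p) < 2:
        raise InsufficientDataError("trace has fewer than 2 samples")
    mean = float(np.trapezoid(p, t) / (t[-1] - t[0]))
    span = float(p.max() - p.min())
    if span <= 1e-9 * max(1.0, abs(mean)):
        return WaveformSummary(
            systolic=mean, diastolic=mean, amplitude=0.0, mean=mean, period=math.nan
        )
    sys_p, dia_p, period = _cycle_extrema(t, p)
    return WaveformSummary(
        systolic=sys_p,
        diastolic=dia_p,
        amplitude=sys_p - dia_p,
        mean=mean,
        period=period,
    )
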