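"""Lumped RC loop: pump waveforms, integration, waveform summaries."""

import math

import numpy as np
import pytest

from lysisflow.errors import InsufficientDataError, InvalidGeometryError
from lysisflow.loop_simulator import (
    DampenerSpec,
    LoopLayout,
    PressureTrace,
    PumpWaveform,
    heartbeat_gate,
    pump_flow_waveform,
    simulate_loop,
    summarize_waveform,
)
from lysisflow.scaling_design import TUBING_ID_5_32_IN, ConduitSpec
from lysisflow.units import MMHG_PA

Q = 5.6e-6  # m^3/s, ~913 1/s wall shear in 5/32-in tubing
F = 9.35  # Hz, 187 RPM x 3 rollers


def _simulate(layout, pump, dampener, periods=40, steps_per_period=400):
    f = pump.pulse_frequency
    return simulate_loop(
        layout, pump, dampener, duration=periods / f, dt=1.0 / (steps_per_period * f)
    )


class TestPumpWaveform:
    @pytest.mark.parametrize(
        "shape,kwargs",
        [
            ("rectified_sine", {}),
            ("constant", {}),
            ("gated", {"duty": 0.5}),
            ("gated", {"duty": 0.25}),
            ("sine", {"modulation": 0.3}),
        ],
    )
    def test_mean_flow_preserved(self, shape, kwargs):
        """Every shape time-averages to the programmed mean flow."""
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=2.0, shape=shape, **kwargs)
        t = np.linspace(0.0, 5.0, 200001)  # 10 periods, endpoint-inclusive
        q = pump_flow_waveform(t, pump)
        mean = np.trapezoid(q, t) / (t[-1] - t[0])
        assert mean == pytest.approx(Q, rel=1e-4)

    def test_gated_on_amplitude(self):
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=1.0, shape="gated", duty=0.5)
        assert pump_flow_waveform(0.25, pump) == pytest.approx(2.0 * Q, rel=1e-12)
        assert pump_flow_waveform(0.75, pump) == 0.0

    def test_rectified_sine_peak(self):
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=1.0, shape="rectified_sine")
        assert pump_flow_waveform(0.5, pump) == pytest.approx(
            math.pi / 2.0 * Q, rel=1e-12
        )

    def test_heartbeat_gate(self):
        base = PumpWaveform(mean_flow=Q, pulse_frequency=F, shape="constant")
        gated = heartbeat_gate(base, gate_frequency=1.0, duty=0.5)
        assert gated.pulse_frequency == 1.0
        assert gated.mean_flow == Q
        # 1-s period, 0.5-s on-window at doubled speed
        assert pump_flow_waveform(0.4, gated) == pytest.approx(2.0 * Q)
        assert pump_flow_waveform(0.6, gated) == 0.0

    def test_heartbeat_gate_limit_recovers_ungated(self):
        base = PumpWaveform(mean_flow=Q, pulse_frequency=F, shape="constant")
        nearly = heartbeat_gate(base, gate_frequency=1.0, duty=0.999)
        t = np.linspace(0.0, 0.998, 500)
        assert np.allclose(pump_flow_waveform(t, nearly), Q / 0.999, rtol=1e-12)

    def test_gate_duty_validation(self):
        base = PumpWaveform(mean_flow=Q, pulse_frequency=F)
        for duty in (0.0, 1.0, 1.5):
            with pytest.raises(InvalidGeometryError):
                heartbeat_gate(base, 1.0, duty)


class TestSimulateLoop:
    def test_constant_pump_steady_state(self, bench_layout, dampener_60ml):
        """Flat input settles to P_B = P_res + R_down * Q within 0.1%."""
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=F, shape="constant")
        trace = _simulate(bench_layout, pump, dampener_60ml)
        expected = (
            bench_layout.reservoir_pressure
            + bench_layout.downstream_resistance * Q
        )
        assert np.allclose(trace.pressure_b, expected, rtol=1e-3)
        s = summarize_waveform(trace, "B")
        assert s.amplitude == 0.0
        assert s.systolic == pytest.approx(s.mean)

    def test_small_signal_matches_rc_filter(self, bench_layout, dampener_60ml):
        """Sinusoidal amplitude is attenuated by 1/sqrt(1+(2 pi f R C)^2)."""
        m = 0.2
        pump = PumpWaveform(
            mean_flow=Q, pulse_frequency=F, shape="sine", modulation=m
        )
        trace = _simulate(bench_layout, pump, dampener_60ml, periods=60, steps_per_period=500)
        s = summarize_waveform(trace, "B")
        r_tot = bench_layout.total_resistance
        c = dampener_60ml.compliance
        gain = 1.0 / math.sqrt(1.0 + (2.0 * math.pi * F * r_tot * c) ** 2)
        predicted = 2.0 * m * Q * bench_layout.downstream_resistance * gain
        assert s.amplitude == pytest.approx(predicted, rel=0.02)

    def test_amplitude_increases_as_air_volume_drops(self, bench_layout):
        """60 -> 5 -> 1 mL air: pulse amplitude at sensor B strictly rises."""
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=F, shape="rectified_sine")
        amps = []
        for v_a in (60e-6, 5e-6, 1e-6):
            damp = DampenerSpec(syringe_capacity=60e-6, air_volume=v_a)
            trace = _simulate(bench_layout, pump, damp)
            amps.append(summarize_waveform(trace, "B").amplitude)
        assert amps[0] < amps[1] < amps[2]

    def test_amplitude_monotone_over_sweep(self, bench_layout):
        """Amplitude at B is monotone non-increasing in air volume (10 points)."""
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=F, shape="rectified_sine")
        volumes = np.geomspace(1e-6, 60e-6, 10)
        amps = []
        for v_a in volumes:
            damp = DampenerSpec(syringe_capacity=60e-6, air_volume=float(v_a))
            amps.append(summarize_waveform(_simulate(bench_layout, pump, damp), "B").amplitude)
        assert all(a1 >= a2 - 1e-12 for a1, a2 in zip(amps, amps[1:]))

    def test_mean_pressure_is_reservoir_plus_resistive_drop(self, bench_layout):
        damp = DampenerSpec(syringe_capacity=60e-6, air_volume=5e-6)
        expected = (
            bench_layout.reservoir_pressure
            + bench_layout.downstream_resistance * Q
        )
        for shape in ("rectified_sine", "constant", "gated"):
            pump = PumpWaveform(
                mean_flow=Q, pulse_frequency=F, shape=shape, duty=0.5
            )
            s = summarize_waveform(_simulate(bench_layout, pump, damp), "B")
            assert s.mean == pytest.approx(expected, rel=5e-3)

    def test_volume_conservation_over_period(self, bench_layout, dampener_60ml):
        """Net dampener volume change over one steady cycle << stroke volume."""
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=F, shape="rectified_sine")
        trace = _simulate(bench_layout, pump, dampener_60ml, periods=60, steps_per_period=500)
        # node pressure P1 = P_A + R_up * Q_out; reconstruct from the trace
        r_up, r_down = bench_layout.upstream_resistance, bench_layout.downstream_resistance
        q_out = (trace.pressure_b - bench_layout.reservoir_pressure) / r_down
        p1 = trace.pressure_a + r_up * q_out
        steps = int(round(1.0 / F / (trace.time[1] - trace.time[0])))
        dv = dampener_60ml.compliance * abs(p1[-1] - p1[-1 - steps])
        stroke = Q / F
        assert dv <= 1e-4 * stroke

    def test_dt_convergence(self, bench_layout, dampener_60ml):
        """Halving dt changes the reported amplitude by < 0.1%."""
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=F, shape="rectified_sine")
        a1 = summarize_waveform(
            _simulate(bench_layout, pump, dampener_60ml, steps_per_period=400), "B"
        ).amplitude
        a2 = summarize_waveform(
            _simulate(bench_layout, pump, dampener_60ml, steps_per_period=800), "B"
        ).amplitude
        assert abs(a1 - a2) / a2 < 1e-3

    def test_coarse_dt_rejected(self, bench_layout, dampener_60ml):
        pump = PumpWaveform(mean_flow=Q, pulse_frequency=F)
        with pytest.raises(InvalidGeometryError, match="dt"):
            simulate_loop(bench_layout, pump, dampener_60ml, duration=2.0, dt=0.01)

    def test_systolic_mean_diastolic_ordering(self, bench_layout):
        """Random settings always give systolic >= mean >= diastolic."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            pump = PumpWaveform(
                mean_flow=float(rng.uniform(1e-6, 8e-6)),
                pulse_frequency=float(rng.uniform(2.0, 12.0)),
                shape=str(rng.choice(["rectified_sine", "gated", "sine"])),
                duty=0.5,
            )
            damp = DampenerSpec(
                syringe_capacity=60e-6, air_volume=float(rng.uniform(1e-6, 60e-6))
            )
            trace = _simulate(bench_layout, pump, damp, periods=30)
            for sensor in ("A", "B"):
                s = summarize_waveform(trace, sensor)
                assert s.systolic >= s.mean - 1e-9 >= s.diastolic - 2e-9
                assert s.amplitude >= 0.0


class TestSummarizeWaveform:
    def test_pure_sine_in_mmhg(self):
        """12 + 2 sin(2 pi t) mmHg -> sys 14, dia 10, amp 4, mean 12."""
        t = np.linspace(0.0, 10.0, 20001)
        p = (12.0 + 2.0 * np.sin(2.0 * math.pi * t)) * MMHG_PA
        trace = PressureTrace(time=t, pressure_a=p, pressure_b=p)
        s = summarize_waveform(trace, "B")
        assert s.systolic / MMHG_PA == pytest.approx(14.0, abs=1e-3)
        assert s.diastolic / MMHG_PA == pytest.approx(10.0, abs=1e-3)
        assert s.amplitude / MMHG_PA == pytest.approx(4.0, abs=2e-3)
        assert s.mean / MMHG_PA == pytest.approx(12.0, abs=1e-3)
        assert s.period == pytest.approx(1.0, abs=1e-3)

    def test_constant_trace(self):
        t = np.linspace(0.0, 5.0, 101)
        p = np.full_like(t, 1600.0)
        s = summarize_waveform(PressureTrace(time=t, pressure_a=p, pressure_b=p), "A")
        assert s.amplitude == 0.0
        assert s.systolic == s.diastolic == pytest.approx(1600.0)
        assert math.isnan(s.period)

    def test_too_short_trace(self):
        t = np.linspace(0.0, 1.0, 101)
        p = 1600.0 + 10.0 * np.sin(2.0 * math.pi * t)  # one period only
        with pytest.raises(InsufficientDataError):
            summarize_waveform(PressureTrace(time=t, pressure_a=p, pressure_b=p), "B")
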