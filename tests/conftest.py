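import pytest

from lysisflow.loop_simulator import DampenerSpec, LoopLayout
from lysisflow.scaling_design import (
    TUBING_ID_5_32_IN,
    ConduitSpec,
    FluidSpec,
)


@pytest.fixture(scope="session")
def plasma() -> FluidSpec:
    """Pooled plasma at 37 C: rho 1025 kg/m^3, mu 1.3 mPa.s."""
    return FluidSpec(density=1025.0, kinematic_viscosity=1.3e-3 / 1025.0)


@pytest.fixture(scope="session")
def water_like() -> FluidSpec:
    return FluidSpec(density=1000.0, kinematic_viscosity=1e-6)


@pytest.fixture
def bench_layout(plasma) -> LoopLayout:
    """Default tubing layout: 36 cm entrance run, 20 cm return, 2x clot."""
    return LoopLayout(
        upstream_segment=ConduitSpec(diameter=TUBING_ID_5_32_IN, length=0.36),
        downstream_segment=ConduitSpec(diameter=TUBING_ID_5_32_IN, length=0.20),
        fluid=plasma,
        clot_resistance_factor=2.0,
    )


@pytest.fixture
def dampener_60ml() -> DampenerSpec:
    return DampenerSpec(syringe_capacity=60e-6, air_volume=60e-6)
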