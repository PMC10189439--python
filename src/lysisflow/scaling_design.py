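"""Dimensionless flow characterization and similarity scaling.

A bench flow loop can reproduce the kinematics of a target vessel (here
typically the human main pulmonary artery, MPA) when the governing
dimensionless groups match.  For pulsatile pipe flow these are the
Reynolds number

    Re = 4 Q / (pi D nu)            (inertial / viscous forces)

the Womersley number

    alpha = (D/2) sqrt(2 pi f / nu) (oscillatory inertia / viscous forces)

and, for wall effects, the laminar Fanning friction factor f_F = 16/Re.
The matching conditions use the groups G_Re = Q/(D nu) and
G_Wo = D^2 f / nu; any constant factor in the Re or alpha convention
cancels, so matching G_Re and G_Wo is equivalent to matching Re and
alpha.  Together with a peristaltic pump law Q = k f (volume per
pulsation cycle times pulse frequency) the three equations have a unique
positive closed-form solution for the model diameter, flow and
frequency:

    D_m = (k G_Wo / G_Re)^(1/3)
    f_m = G_Wo nu_m / D_m^2
    Q_m = k f_m

The module also provides the standard laminar tube relations used to set
and verify bench conditions: Poiseuille wall shear rate 32 Q/(pi D^3),
Chandler-loop drum shear, Hagen-Poiseuille pressure drop, hydrostatic
head and laminar entrance length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import (
    InvalidCalibrationError,
    InvalidFluidError,
    InvalidGeometryError,
    InvalidPumpError,
)
from .units import STANDARD_GRAVITY

__all__ = [
    "FluidSpec",
    "ConduitSpec",
    "TargetVessel",
    "PumpLaw",
    "DimensionlessProfile",
    "SimilarityDesign",
    "dimensionless_profile",
    "wall_shear_tube",
    "chandler_wall_shear",
    "shear_from_rpm",
    "solve_similarity",
    "hagen_poiseuille_dp",
    "hydrostatic_dp",
    "entrance_length",
    "LAMINAR_RE_LIMIT",
    "TUBING_ID_5_32_IN",
    "BLOOD_PLASMA",
]

LAMINAR_RE_LIMIT = 2100.0
TUBING_ID_5_32_IN = 3.9688e-3  # 5/32 in Tygon lumen, metres


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian working fluid.

    Parameters
    ----------
    density :
        Mass density rho, kg/m^3.
    kinematic_viscosity :
        nu, m^2/s.
    dynamic_viscosity :
        mu = rho * nu, Pa.s.  Derived automatically when omitted; if
        supplied it must agree with rho*nu to 1e-12 relative.
    """

    density: float
    kinematic_viscosity: float
    dynamic_viscosity: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise InvalidFluidError("density and kinematic viscosity must be positive")
        mu = self.density * self.kinematic_viscosity
        if self.dynamic_viscosity is None:
            object.__setattr__(self, "dynamic_viscosity", mu)
        else:
            if self.dynamic_viscosity <= 0:
                raise InvalidFluidError("dynamic viscosity must be positive")
            if abs(self.dynamic_viscosity - mu) > 1e-12 * mu:
                raise InvalidFluidError(
                    f"inconsistent viscosities: mu={self.dynamic_viscosity} "
                    f"but rho*nu={mu}"
                )


#: Pooled human plasma at 37 C (rho 1025 kg/m^3, mu 1.3 mPa.s).
BLOOD_PLASMA = FluidSpec(density=1025.0, kinematic_viscosity=1.3e-3 / 1025.0)


@dataclass(frozen=True)
class ConduitSpec:
    """A straight circular tube segment: lumen diameter and length, metres."""

    diameter: float
    length: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidGeometryError(f"diameter must be > 0, got {self.diameter}")
        if self.length < 0:
            raise InvalidGeometryError(f"length must be >= 0, got {self.length}")


@dataclass(frozen=True)
class TargetVessel:
    """Hemodynamic description of the vessel being mimicked (SI units)."""

    diameter: float  # m
    mean_flow: float  # m^3/s, averaged over a cardiac cycle
    pulse_frequency: float  # Hz
    fluid: FluidSpec
    mean_pressure: float  # Pa

    def __post_init__(self) -> None:
        for name in ("diameter", "mean_flow", "pulse_frequency", "mean_pressure"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")


@dataclass(frozen=True)
class PumpLaw:
    """Peristaltic pump characteristic.

    ``volume_per_cycle`` k links mean flow to pulse frequency via
    Q = k f.  The pulse frequency itself is rollers x RPM / 60.  An
    optional empirical shear-per-RPM constant carries a bench
    calibration that need not be consistent with k (tubing compression
    is not ideal).
    """

    volume_per_cycle: float  # m^3 per pulsation cycle
    rollers: int = 3
    empirical_shear_per_rpm: float | None = None  # s^-1 per RPM

    def __post_init__(self) -> None:
        if self.volume_per_cycle <= 0:
            raise InvalidPumpError("volume_per_cycle must be positive")
        if self.rollers < 1:
            raise InvalidPumpError("rollers must be >= 1")
        if self.empirical_shear_per_rpm is not None and self.empirical_shear_per_rpm <= 0:
            raise InvalidPumpError("empirical_shear_per_rpm must be positive")

    def pulse_frequency(self, rpm: float) -> float:
        """Pulsation frequency (Hz) at a given pump speed."""
        return self.rollers * rpm / 60.0


@dataclass(frozen=True)
class DimensionlessProfile:
    """Dimensionless groups of a steady or pulsatile tube flow."""

    reynolds: float
    womersley: float
    wall_shear: float  # s^-1
    fanning: float | None = None  # 16/Re, laminar; None at zero flow

    def __post_init__(self) -> None:
        if self.reynolds < 0 or self.womersley < 0 or self.wall_shear < 0:
            raise InvalidGeometryError("dimensionless groups must be non-negative")


@dataclass(frozen=True)
class SimilarityDesign:
    """Solved bench-loop operating point plus its matched groups."""

    model_diameter: float  # m
    model_flow: float  # m^3/s
    model_frequency: float  # Hz
    profile: DimensionlessProfile
    re_group_residual: float = field(default=0.0)
    wo_group_residual: float = field(default=0.0)


def _require_positive_diameter(D: float) -> None:
    if D <= 0:
        raise InvalidGeometryError(f"diameter must be > 0, got {D}")


def _warn_if_turbulent(re: float) -> None:
    if re > LAMINAR_RE_LIMIT:
        warnings.warn(
            f"Re = {re:.0f} exceeds the laminar limit {LAMINAR_RE_LIMIT:.0f}; "
            "laminar relations (wall shear, Fanning, Hagen-Poiseuille) are "
            "extrapolations here",
            stacklevel=3,
        )


def dimensionless_profile(
    Q: float, D: float, f: float, fluid: FluidSpec
) -> DimensionlessProfile:
    """Characterize a tube flow by Re, Womersley number and wall shear.

    Parameters are the mean volumetric flow Q (m^3/s), lumen diameter D
    (m), pulse frequency f (Hz) and the working fluid.
    """
    _require_positive_diameter(D)
    if Q < 0 or f < 0:
        raise InvalidGeometryError("Q and f must be non-negative")
    nu = fluid.kinematic_viscosity
    re = 4.0 * Q / (math.pi * D * nu)
    alpha = (D / 2.0) * math.sqrt(2.0 * math.pi * f / nu)
    gamma = 32.0 * Q / (math.pi * D**3)
    fanning = 16.0 / re if re > 0 else None
    _warn_if_turbulent(re)
    return DimensionlessProfile(reynolds=re, womersley=alpha, wall_shear=gamma, fanning=fanning)


def wall_shear_tube(Q: float, D: float) -> float:
    """Poiseuille wall shear rate 32 Q / (pi D^3) = 8 Vbar / D, s^-1."""
    _require_positive_diameter(D)
    if Q < 0:
        raise InvalidGeometryError(f"Q must be >= 0, got {Q}")
    return 32.0 * Q / (math.pi * D**3)


def chandler_wall_shear(rpm: float, drum_radius: float, D: float) -> float:
    """Wall shear rate in a rotating Chandler loop, s^-1.

    In the Chandler loop the tube rotates while gravity holds the fluid
    slug in place, so the mean fluid velocity relative to the wall equals
    the drum surface speed 2 pi R rpm / 60; the Poiseuille surface
    relation 8 Vbar / D then gives the wall shear rate.
    """
    _require_positive_diameter(D)
    if drum_radius <= 0:
        raise InvalidGeometryError(f"drum_radius must be > 0, got {drum_radius}")
    if rpm < 0:
        raise InvalidGeometryError(f"rpm must be >= 0, got {rpm}")
    v_bar = 2.0 * math.pi * drum_radius * rpm / 60.0
    return 8.0 * v_bar / D


def shear_from_rpm(rpm: float, anchor: tuple[float, float]) -> float:
    """Proportional pump-speed-to-shear calibration.

    ``anchor`` is a measured (rpm0, shear0) pair; the peristaltic pump is
    volumetrically linear in speed, so shear scales as
    gamma = (shear0/rpm0) * rpm.
    """
    rpm0, shear0 = anchor
    if rpm0 <= 0 or shear0 <= 0:
        raise InvalidCalibrationError(f"anchor must be positive, got {anchor}")
    if rpm < 0:
        raise InvalidCalibrationError(f"rpm must be >= 0, got {rpm}")
    return shear0 / rpm0 * rpm


def solve_similarity(
    target: TargetVessel, model_fluid: FluidSpec, pump: PumpLaw
) -> SimilarityDesign:
    """Solve the three similarity equations for the bench loop.

    Matches the Reynolds group Q/(D nu) and the Womersley group
    D^2 f / nu of the target vessel subject to the pump constraint
    Q_m = k f_m.  The closed-form positive solution is

        D_m = (k G_Wo / G_Re)^(1/3),  f_m = G_Wo nu_m / D_m^2,  Q_m = k f_m.

    Residuals of both matched groups are recomputed from the returned
    operating point and are zero to rounding (<= 1e-9 relative).
    """
    k = pump.volume_per_cycle
    if k <= 0:  # defensive; PumpLaw already validates
        raise InvalidPumpError("volume_per_cycle must be positive")
    nu_t = target.fluid.kinematic_viscosity
    nu_m = model_fluid.kinematic_viscosity
    g_re = target.mean_flow / (target.diameter * nu_t)
    g_wo = target.diameter**2 * target.pulse_frequency / nu_t

    d_m = (k * g_wo / g_re) ** (1.0 / 3.0)
    f_m = g_wo * nu_m / d_m**2
    q_m = k * f_m

    re_resid = abs(q_m / (d_m * nu_m) - g_re) / g_re
    wo_resid = abs(d_m**2 * f_m / nu_m - g_wo) / g_wo
    profile = dimensionless_profile(q_m, d_m, f_m, model_fluid)
    return SimilarityDesign(
        model_diameter=d_m,
        model_flow=q_m,
        model_frequency=f_m,
        profile=profile,
        re_group_residual=re_resid,
        wo_group_residual=wo_resid,
    )


def hagen_poiseuille_dp(Q: float, conduit: ConduitSpec, fluid: FluidSpec) -> float:
    """Laminar pressure drop over a tube segment, Pa.

    Hagen-Poiseuille: dP = 128 mu L Q / (pi D^4).  Algebraically
    identical to the Fanning form 2 f_F rho Vbar^2 L / D with f_F = 16/Re.
    """
    if Q < 0:
        raise InvalidGeometryError(f"Q must be >= 0, got {Q}")
    D, L = conduit.diameter, conduit.length
    mu = fluid.dynamic_viscosity
    assert mu is not None
    if Q > 0:
        _warn_if_turbulent(4.0 * Q / (math.pi * D * fluid.kinematic_viscosity))
    return 128.0 * mu * L * Q / (math.pi * D**4)


def poiseuille_resistance(conduit: ConduitSpec, fluid: FluidSpec) -> float:
    """Hydraulic resistance dP/Q = 128 mu L / (pi D^4), Pa.s/m^3."""
    mu = fluid.dynamic_viscosity
    assert mu is not None
    return 128.0 * mu * conduit.length / (math.pi * conduit.diameter**4)


def hydrostatic_dp(height: float, fluid: FluidSpec) -> float:
    """Hydrostatic pressure rho g h of an elevated reservoir, Pa."""
    if height < 0:
        raise InvalidGeometryError(f"height must be >= 0, got {height}")
    return fluid.density * STANDARD_GRAVITY * height


def entrance_length(Re: float, D: float) -> float:
    """Laminar hydrodynamic entrance length L_e = 0.06 Re D, metres.

    The clot analog must sit at least this far downstream of the last
    fitting for the parabolic profile (and hence the nominal wall shear)
    to be fully developed.
    """
    _require_positive_diameter(D)
    if Re < 0:
        raise InvalidGeometryError(f"Re must be >= 0, got {Re}")
    return 0.06 * Re * D
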