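"""Reagent calculators for fluorescent clot-analog preparation.

Clot analogs are labelled by spiking FITC-conjugated fibrinogen
(FITC-Fg) into whole blood or plasma at a chosen ratio r of native
fibrinogen to FITC-Fg; citrated blood is then recalcified with CaCl2 to
initiate clotting.  These are straight mixing calculations, kept here
so the bench numbers (spike concentration in mg/mL and uM, CaCl2 stock
volume) come from one audited place.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InfeasibleDilutionError, RatioError

__all__ = [
    "LabelingPlan",
    "SpikeResult",
    "spike_concentration",
    "recalcification_volume",
]


@dataclass(frozen=True)
class LabelingPlan:
    """Fibrinogen labelling plan.

    ``ratio`` r is native Fg : FITC-Fg, so the spike concentration is
    native/r.  Defaults: 3 mg/mL native fibrinogen (pooled whole
    blood), 14 FITC per fibrinogen, molar mass 340 kDa.
    """

    native_fg_conc: float = 3.0  # mg/mL
    ratio: float = 10.0  # native Fg : FITC-Fg
    fitc_per_fg: float = 14.0  # labels per molecule
    fibrinogen_mw: float = 340.0  # kDa

    def __post_init__(self) -> None:
        if min(self.native_fg_conc, self.fitc_per_fg, self.fibrinogen_mw) <= 0:
            raise RatioError("plan quantities must be positive")
        if self.ratio < 1:
            raise RatioError(f"ratio must be >= 1, got {self.ratio}")


@dataclass(frozen=True)
class SpikeResult:
    """Exogenous FITC-Fg concentration in mass and molar units."""

    exo_conc: float  # mg/mL
    exo_molar: float  # uM


def spike_concentration(plan: LabelingPlan) -> SpikeResult:
    """FITC-Fg spike concentration for a labelling plan.

    exo (mg/mL) = native / r; molar (uM) = exo (g/L) / MW (g/mol) * 1e6.
    """
    exo = plan.native_fg_conc / plan.ratio
    exo_molar = exo / (plan.fibrinogen_mw * 1e3) * 1e6  # mg/mL == g/L
    return SpikeResult(exo_conc=exo, exo_molar=exo_molar)


def recalcification_volume(
    stock_conc: float, sample_volume: float, target_conc: float
) -> float:
    """CaCl2 stock volume (mL) bringing a sample to the target concentration.

    Solves target = stock*v / (V + v) for v, accounting for the
    dilution by the added stock itself:  v = target*V / (stock - target).
    """
    if target_conc < 0:
        raise InfeasibleDilutionError("target_conc must be >= 0")
    if sample_volume <= 0:
        raise InfeasibleDilutionError("sample_volume must be positive")
    if target_conc == 0:
        return 0.0
    if stock_conc <= target_conc:
        raise InfeasibleDilutionError(
            f"stock ({stock_conc} mM) must exceed target ({target_conc} mM)"
        )
    return target_conc * sample_volume / (stock_conc - target_conc)


def dilution_concentration(
    stock_conc: float, stock_volume: float, total_volume: float
) -> float:
    """Final concentration after mixing stock into a total volume."""
    if total_volume <= 0 or stock_volume < 0:
        raise InfeasibleDilutionError("volumes must be positive")
    return stock_conc * stock_volume / total_volume
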