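"""Exception hierarchy shared across the package."""


class LysisflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(LysisflowError, ValueError):
    """A diameter, radius or length is non-positive or otherwise unusable."""


class InvalidFluidError(LysisflowError, ValueError):
    """Fluid properties are non-positive or mutually inconsistent."""


class InvalidCalibrationError(LysisflowError, ValueError):
    """A calibration anchor (e.g. RPM/shear pair) is unusable."""


class InvalidPumpError(LysisflowError, ValueError):
    """Pump-law parameters are non-positive or inconsistent."""


class IntegrationError(LysisflowError, RuntimeError):
    """The loop integrator produced a non-finite state."""


class InsufficientDataError(LysisflowError, ValueError):
    """A trace is too short for the requested analysis."""


class PresetError(LysisflowError, KeyError):
    """Unknown preset name; the message lists the available catalog."""


class TraceFormatError(LysisflowError, ValueError):
    """A trace file violates the CSV contract (header, monotonic time)."""


class ConversionError(LysisflowError, ValueError):
    """Unknown unit or dimensionally incompatible unit pair."""


class ConfigError(LysisflowError, ValueError):
    """Device configuration is malformed (e.g. unit tag missing)."""


class UndefinedCOVError(LysisflowError, ZeroDivisionError):
    """COV requested where mean is zero but spread is not."""


class UndefinedCorrelationError(LysisflowError, ValueError):
    """Pearson correlation requested on constant input."""


class RatioError(LysisflowError, ValueError):
    """Labeling ratio outside the supported range."""


class InfeasibleDilutionError(LysisflowError, ValueError):
    """Stock concentration does not exceed the dilution target."""


class NegativeLossError(LysisflowError, ValueError):
    """Post-digestion mass exceeds pre-digestion mass."""
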