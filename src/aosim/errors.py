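"""Exception hierarchy for aosim."""


class AosimError(Exception):
    """Base class for all aosim errors."""


class ConfigurationError(AosimError, ValueError):
    """Invalid optical or run configuration."""


class ShapeError(AosimError, ValueError):
    """Mismatched grids or array shapes."""


class DegenerateInputError(AosimError, ValueError):
    """Input carries no usable signal (e.g. all-zero image, empty spot list)."""


class DetectionError(AosimError, RuntimeError):
    """Fewer spot candidates found than requested."""

    def __init__(self, message: str, found: int = 0):
        super().__init__(message)
        self.found = found


class RangeError(AosimError, RuntimeError):
    """Axial scan range too small to satisfy a criterion."""

    def __init__(self, message: str, achieved_ratio: float = float("nan")):
        super().__init__(message)
        self.achieved_ratio = achieved_ratio


class ResolutionError(AosimError, ValueError):
    """Pupil grid too coarse for the requested sensor geometry."""


class LayoutError(AosimError, ValueError):
    """Actuator layout inconsistent with the pupil."""


class CalibrationError(AosimError, RuntimeError):
    """Degenerate modal calibration (no usable modes)."""


class AmbiguityError(AosimError, RuntimeError):
    """Displacement-mode identification is ambiguous."""

    def __init__(self, message: str, correlation_table=None):
        super().__init__(message)
        self.correlation_table = correlation_table


class UsageError(AosimError, ValueError):
    """Operation invoked on an invalid mode or argument combination."""


class QuadraticFitError(AosimError, RuntimeError):
    """Three-point quadratic fit is non-convex or degenerate."""


class CorrectionStalledError(AosimError, RuntimeError):
    """Every mode's quadratic fit failed within one iteration."""


class SurfaceFitError(AosimError, RuntimeError):
    """Nonlinear cross-term surface fit failed to converge."""
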