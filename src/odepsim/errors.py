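"""Exception hierarchy shared across the package."""


class OdepSimError(Exception):
    """Base class for all package errors."""


class ValidationError(OdepSimError, ValueError):
    """Invalid user input: bad dimensions, fractions, configuration keys."""


class ResolutionError(ValidationError):
    """Grid spacing too coarse for the requested geometry."""


class NumericalError(OdepSimError, RuntimeError):
    """Solver failure; carries a residual report when available."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CalibrationError(OdepSimError, RuntimeError):
    """Force-model or threshold calibration could not satisfy its anchors."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class PlacementError(OdepSimError, RuntimeError):
    """Cell staging failed: the isolation zone is too crowded."""
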