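"""Exception types shared across the package."""


class AvpvkError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(AvpvkError):
    """A gating/conductance specification violates its invariants."""


class CalibrationError(AvpvkError):
    """Leak/holding-current calibration could not satisfy its targets."""


class IntegrationError(AvpvkError):
    """Numerical integration produced non-finite state."""


class GridMismatchError(AvpvkError):
    """Two traces expected on the same sample grid differ."""


class FitError(AvpvkError):
    """Curve fitting failed to converge or the data are degenerate."""


class DegenerateError(AvpvkError):
    """A linear-algebra step hit a (numerically) singular system."""
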