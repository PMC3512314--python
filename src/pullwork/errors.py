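"""Exception hierarchy shared across the package."""


class PullworkError(Exception):
    """Base class for all package errors."""


class ValidationError(PullworkError, ValueError):
    """Invalid configuration or argument values."""


class StabilityError(PullworkError):
    """Integrator time step too large for the stiffest timescale present."""


class ParseError(PullworkError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class GeometryError(PullworkError):
    """Degenerate geometry: coincident points, collinear plane vertices."""


class AlignmentError(PullworkError):
    """Force/position time grids cannot be paired within tolerance."""


class ConvergenceError(PullworkError):
    """A convergence criterion could not be satisfied by the data."""
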