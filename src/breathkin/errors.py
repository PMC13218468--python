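"""Exception hierarchy for the pipeline."""


class BreathkinError(Exception):
    """Base class for all package errors."""


class FormatError(BreathkinError, ValueError):
    """A file violates its declared format (bad WAV header, xmin > xmax, ...)."""


class ParseError(FormatError):
    """A delimited table row could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SpecError(BreathkinError, ValueError):
    """Invalid simulation specification (overlapping cycles, bad rates, ...)."""


class ConfigurationError(BreathkinError, ValueError):
    """Invalid analysis configuration (missing sensor role, conflicting inputs)."""


class DegenerateInputError(BreathkinError, ValueError):
    """Formally valid but analytically degenerate input (all-zero signal,
    zero-variance cycle, empty window intersection, ...)."""


class DetectionError(BreathkinError, RuntimeError):
    """An event that must exist could not be found (e.g. silent sync track)."""


class AlignmentError(BreathkinError, RuntimeError):
    """Streams share no common support after synchronization."""


class LandmarkValidationError(BreathkinError, ValueError):
    """Manual landmark overrides violate the onset < offset < end ordering."""
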