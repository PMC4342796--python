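"""Exception hierarchy shared across the package."""


class MarkcastError(Exception):
    """Base class for all package-specific errors."""


class BedParseError(MarkcastError):
    """A BED line could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class BoundsError(MarkcastError):
    """A region extends beyond its chromosome or names an unknown chromosome."""


class ConfigurationError(MarkcastError):
    """Invalid simulation/classifier/experiment configuration."""


class SamplingExhaustedError(MarkcastError):
    """A matched negative could not be placed within the allowed attempts."""


class SelectionError(MarkcastError):
    """A feature-selection predicate matched no columns."""


class EvaluationError(MarkcastError):
    """Invalid input to an evaluation routine (e.g. single-class labels)."""
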