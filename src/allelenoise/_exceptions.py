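"""Exception hierarchy shared across the package."""


class AlleleNoiseError(Exception):
    """Base class for all package errors."""


class ParameterError(AlleleNoiseError, ValueError):
    """An input parameter is outside its documented domain.

    The message always names the offending field.
    """


class DegenerateInputError(AlleleNoiseError, ValueError):
    """Input data are structurally valid but degenerate for the requested
    computation (e.g. a nonpositive experiment mean before normalization)."""


class EmptyGroupError(AlleleNoiseError, ValueError):
    """A group required to be non-empty contained no observations."""


class GeometryError(AlleleNoiseError, ValueError):
    """Requested scene geometry cannot be realised (e.g. nuclei overlap)."""


class StackFormatError(AlleleNoiseError, ValueError):
    """An image stack does not conform to the two-channel ZCYX contract."""


class GFF3ParseError(AlleleNoiseError, ValueError):
    """Malformed GFF3 input; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(AlleleNoiseError, ValueError):
    """A pipeline run configuration violates the documented schema."""
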