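"""Exception hierarchy for the package.

Every error raised by the library derives from :class:`NdjScreenError`, so
callers (and the CLI) can catch one base class. Subclasses mirror the failure
modes of the individual stages: parameter validation, degenerate models,
undefined estimates, malformed input tables, cytogenetic parse failures, and
inconsistent screen data.
"""


class NdjScreenError(Exception):
    """Base class for all errors raised by ndjscreen."""


class ParameterError(NdjScreenError, ValueError):
    """A model or operation parameter is outside its valid range."""


class DegenerateModelError(NdjScreenError, ValueError):
    """Cross parameterization under which no zygote class can survive."""


class UndefinedEstimateError(NdjScreenError, ValueError):
    """Estimate requested from counts with zero adjusted total."""


class InsufficientDataError(NdjScreenError, ValueError):
    """Too few observations for the requested summary (e.g. < 2 controls)."""


class ConfigurationError(NdjScreenError, ValueError):
    """Inconsistent call or pipeline configuration (e.g. missing control)."""


class TableFormatError(NdjScreenError, ValueError):
    """A count table violates the expected TSV schema."""


class CytoParseError(NdjScreenError, ValueError):
    """Malformed cytogenetic breakpoint text; carries the offending position."""

    def __init__(self, message: str, text: str = "", position: int | None = None):
        self.text = text
        self.position = position
        if position is not None:
            message = f"{message} (in {text!r} at position {position})"
        super().__init__(message)


class UnsupportedRearrangementError(CytoParseError):
    """Breakpoint string with more than two breakpoints (complex aberration).

    Flagged separately from plain parse errors so pipelines can skip such
    rows instead of aborting.
    """


class NoConsistentRegionError(NdjScreenError, ValueError):
    """Candidate-region inference eliminated every band (inconsistent data)."""
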