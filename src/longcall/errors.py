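"""Exception hierarchy for the longcall package.

All package-specific failures derive from :class:`LongCallError` so callers
(and the CLI) can distinguish data/usage problems from genuine bugs.
"""


class LongCallError(Exception):
    """Base class for all longcall errors."""


class SchemaError(LongCallError):
    """A required column is missing or a file's layout cannot be interpreted."""


class RowParseError(LongCallError):
    """A cell value could not be parsed; carries the offending row numbers."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class ValidationError(LongCallError):
    """An event table violates a structural invariant that cannot be repaired."""


class InsufficientDataError(LongCallError):
    """Too few observations to carry out the requested computation."""


class DesignError(LongCallError):
    """A factorial design does not support the requested analysis."""


class GenerationError(LongCallError):
    """A synthetic-data specification is infeasible."""


class ModelError(LongCallError):
    """Degenerate input to a statistical model (e.g. all-zero counts)."""


class FitError(LongCallError):
    """A model fit failed to converge under every available strategy."""
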