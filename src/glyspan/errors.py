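"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration problems (2),
data problems (3), anything else (1).
"""


class GlyspanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlyspanError):
    """Invalid configuration: bad parameters, missing models, bad ratios."""


class DataValidationError(GlyspanError):
    """Input data violates the documented contract."""

    def __init__(self, message, row_errors=None):
        super().__init__(message)
        #: list of (line_number, message) pairs for row-level diagnostics
        self.row_errors = list(row_errors or [])


class DegenerateDataError(GlyspanError):
    """Statistically degenerate input (constant vector, zero margin, ...)."""
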