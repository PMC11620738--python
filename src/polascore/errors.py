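"""Exception hierarchy shared across the package."""


class PolascoreError(Exception):
    """Base class for all package errors."""


class SchemaError(PolascoreError):
    """A required column is missing or a header is malformed."""


class RowValidationError(PolascoreError):
    """A data row violates a field invariant.

    Attributes
    ----------
    row_number : int
        1-based line number of the offending row in the source file
        (counting the header and comment lines).
    """

    def __init__(self, message: str, row_number: int | None = None):
        super().__init__(message)
        self.row_number = row_number


class InsufficientDataError(PolascoreError):
    """Too few observations for the requested fit or test."""


class DegenerateDesignError(PolascoreError):
    """Regression design matrix is singular (e.g. all x identical)."""


class InputMixError(PolascoreError):
    """Input contains rows from an unexpected reporter or group."""


class ModelError(PolascoreError):
    """Calibration model is unfitted, degenerate, or inconsistent."""


class DegenerateTableError(PolascoreError):
    """Contingency table has a zero row margin."""


class DegenerateVarianceError(PolascoreError):
    """Pooled variance is zero; the t statistic is undefined."""


class ConfigError(PolascoreError):
    """Invalid simulation or pipeline configuration."""
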