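"""Exception hierarchy shared across the package."""


class CircamarkError(Exception):
    """Base class for all package errors."""


class ParameterError(CircamarkError, ValueError):
    """Invalid simulation or analysis parameters."""


class InsufficientDataError(CircamarkError, ValueError):
    """Too little data for the requested computation (e.g. < 24 h actigraphy)."""


class EligibilityError(InsufficientDataError):
    """Patient does not meet the minimum-sample eligibility rule."""


class DegenerateDataError(CircamarkError, ValueError):
    """Input is structurally degenerate (constant series, singular design)."""


class SchemaError(CircamarkError, ValueError):
    """A file violated the expected CSV schema; message names row and column."""
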