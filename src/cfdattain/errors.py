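"""Exception hierarchy for the attainment-assessment pipeline."""


class CfdAttainError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CfdAttainError):
    """Input values violate a precondition (empty lists, out-of-range parameters)."""


class ConsistencyError(CfdAttainError):
    """Records that must share labels (segment, use, date) do not."""


class InsufficientDataError(CfdAttainError):
    """Too few observations to perform the requested computation."""


class FormatError(CfdAttainError):
    """A table or configuration file does not match the expected schema."""


class ConfigurationError(CfdAttainError):
    """Criterion/use mismatch or otherwise inconsistent run configuration."""
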