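"""Exception hierarchy shared across the package."""


class PopscaleError(Exception):
    """Base class for all package errors."""


class FormatError(PopscaleError):
    """A table is malformed: missing column, unparsable field, bad header."""


class ValidationError(PopscaleError):
    """A well-formed row violates a type invariant (bad rate, self-loop...)."""


class DuplicateKeyError(ValidationError):
    """The same key occurs more than once where uniqueness is required."""

    def __init__(self, message, keys=()):
        super().__init__(message)
        self.keys = list(keys)


class ParameterError(PopscaleError):
    """A function argument is outside its documented domain."""


class DegenerateDataError(PopscaleError):
    """Input data cannot support the requested fit (single class, zero spread)."""


class ConsistencyError(PopscaleError):
    """Cross-table references do not line up (unscored variant, missing rate)."""


class NoThresholdError(PopscaleError):
    """No score attains the requested posterior level for this mixture."""
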