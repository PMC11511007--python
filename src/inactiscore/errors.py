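"""Exception hierarchy for inactiscore."""


class InactiscoreError(Exception):
    """Base class for all domain errors raised by this package."""


class EmptyStreamError(InactiscoreError):
    """Raised when an operation that requires events receives none."""


class ConfigurationError(InactiscoreError):
    """Raised for invalid or inconsistent configuration values."""


class InsufficientDataError(InactiscoreError):
    """Raised when a stream is too short for the requested evaluation."""


class NoReferenceError(InactiscoreError):
    """Raised when a threshold query has no usable reference times."""
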