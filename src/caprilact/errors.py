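"""Exception hierarchy shared across the package."""


class CapriLactError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CapriLactError):
    """A configuration object or file violates its invariants."""


class FormatError(CapriLactError):
    """An input file does not have the documented layout."""


class ValidationError(CapriLactError):
    """Input rows or values violate domain invariants."""


class InsufficientDataError(CapriLactError):
    """Too few observations for the requested computation."""


class DomainError(CapriLactError):
    """A model was evaluated outside its mathematical domain."""


class DegenerateDataError(CapriLactError):
    """A statistic is undefined for this input (e.g. zero variance)."""
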