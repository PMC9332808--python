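"""Exception hierarchy shared across the package."""


class VaxDiscourseError(Exception):
    """Base class for all package errors."""


class SchemaError(VaxDiscourseError):
    """An input file is missing required columns or keys."""


class ValidationError(VaxDiscourseError):
    """Input content violates a domain invariant (e.g. negative reactions)."""


class ConfigurationError(VaxDiscourseError):
    """A named pluggable component or parameter is invalid or unregistered."""


class InsufficientDataError(VaxDiscourseError):
    """The input carries too little information for the requested statistic."""


class DegenerateDataError(VaxDiscourseError):
    """The statistic is undefined on this input (e.g. zero expected disagreement)."""
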