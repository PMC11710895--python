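"""Exception hierarchy for the sednet pipeline.

Every error raised by the package derives from :class:`SednetError`, so callers
can catch pipeline failures without masking programming errors.
"""


class SednetError(Exception):
    """Base class for all sednet errors."""


class ParseError(SednetError):
    """A text input could not be parsed (names the offending row/column)."""


class ValidationError(SednetError):
    """An input violated a structural invariant (non-finite value, bad code...)."""


class DimensionError(SednetError):
    """Array shapes are inconsistent with each other or with the configuration."""


class DegenerateSignalError(SednetError):
    """A region's signal has zero variance inside a correlation window."""


class ConfigurationError(SednetError):
    """A parameter combination is invalid (e.g. window guard, unbalanced design)."""
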