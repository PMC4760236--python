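"""Typed exceptions raised across the package.

Every malformed input raises one of these — never a silent skip — so that
batch sweeps can distinguish bad data from bad parameters.
"""


class GroupAlignError(Exception):
    """Base class for all package errors."""


class FormatError(GroupAlignError):
    """A file does not have the expected tabular structure (e.g. missing column)."""


class PeakParseError(GroupAlignError):
    """A field in a peak table could not be parsed (non-numeric m/z, RT, ...)."""


class ValidationError(GroupAlignError):
    """Parsed data violates a domain invariant (duplicate id, unknown id, ...)."""


class ParameterError(GroupAlignError):
    """A configuration value is outside its legal range."""


class DimensionError(GroupAlignError):
    """Matrix shapes do not conform for the requested operation."""
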