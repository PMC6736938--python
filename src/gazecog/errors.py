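"""Exception hierarchy for gazecog.

All package errors derive from :class:`GazecogError` so callers (and the
CLI) can catch validation problems distinctly from programming errors.
"""


class GazecogError(Exception):
    """Base class for all gazecog errors."""


class FormatError(GazecogError):
    """A file does not conform to the expected text format (missing
    columns, unparseable cells, out-of-range coordinates)."""


class DataError(GazecogError):
    """The file parsed but its content violates a data invariant
    (non-monotone timestamps, duplicate subject IDs, unknown group)."""


class ConfigError(GazecogError):
    """A timeline or simulation configuration violates its invariants."""


class ValidationError(GazecogError):
    """An in-memory value is outside its documented domain."""
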