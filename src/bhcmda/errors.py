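"""Exception hierarchy.

All domain errors derive from :class:`BhcmdaError` so the CLI can map any
validation failure to a single exit code.
"""


class BhcmdaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BhcmdaError):
    """Malformed input file (bad field count, non-numeric cell, ...)."""


class ValidationError(BhcmdaError):
    """Structurally valid input that violates a domain invariant."""


class LabelMismatchError(ValidationError):
    """Two labelled objects that must share an axis do not."""
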