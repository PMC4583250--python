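"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`MitoburdenError`, so callers can catch one type at pipeline level.
"""


class MitoburdenError(Exception):
    """Base class for all package errors."""


class ValidationError(MitoburdenError):
    """An input value violates a documented invariant (range, sign, alphabet)."""


class ParseError(MitoburdenError):
    """A text input file is malformed; the message names the offending line."""


class FormatError(MitoburdenError):
    """A structured file (e.g. VCF) lacks a required field; names the record."""
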