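"""Exception hierarchy.

Readers raise :class:`FormatError` for structural problems (missing
columns, ragged matrices), :class:`ParseError` for unparseable cells, and
:class:`DataError` for well-formed input that violates a domain invariant
(non-monotonic scan positions, non-positive doses).  Argument misuse
raises plain :class:`ValueError`/:class:`TypeError` as usual.
"""


class BeamcheckError(Exception):
    """Base class for all beamcheck-specific errors."""


class FormatError(BeamcheckError):
    """A file does not have the expected structure."""


class ParseError(BeamcheckError):
    """A cell or field could not be parsed."""


class DataError(BeamcheckError):
    """Parsed data violates a domain invariant."""


class ConfigurationError(BeamcheckError):
    """A requested analysis cannot be assembled from the given dataset."""
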