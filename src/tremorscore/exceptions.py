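"""Exception hierarchy for tremorscore.

All package errors derive from :class:`TremorScoreError` so callers can
catch everything with one clause; the three subclasses mirror the three
contract families: malformed files, invalid data, invalid parameters.
"""


class TremorScoreError(Exception):
    """Base class for all tremorscore errors."""


class FormatError(TremorScoreError):
    """A file does not conform to the expected on-disk format."""


class DataError(TremorScoreError):
    """Input data violates a pipeline precondition (too short, empty, ...)."""


class ParameterError(TremorScoreError):
    """A configuration or argument value is out of its valid range."""
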