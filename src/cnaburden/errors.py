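"""Exception hierarchy for cnaburden.

All errors raised by the library derive from :class:`CnaBurdenError` so callers
(and the CLI) can distinguish validation problems from genuine bugs.
"""


class CnaBurdenError(Exception):
    """Base class for all cnaburden errors."""


class SchemaError(CnaBurdenError):
    """Input table is missing a mandatory column or has an invalid header."""


class ParseError(CnaBurdenError):
    """A cell value could not be parsed (carries the offending row index)."""


class ValidationError(CnaBurdenError):
    """Input values violate a contract (overlapping segments, bad ranges...)."""


class UnknownBuildError(CnaBurdenError):
    """Requested genome build is not bundled."""


class ConfigError(CnaBurdenError):
    """Inconsistent parameter combination."""


class ProtocolError(CnaBurdenError):
    """The classifier protocol preconditions cannot be satisfied."""
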