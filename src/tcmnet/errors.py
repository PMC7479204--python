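"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`TcmnetError`,
so callers (and the CLI) can catch one type and report the stage that failed.
"""


class TcmnetError(Exception):
    """Base class for all tcmnet errors."""


class ConfigError(TcmnetError):
    """A configuration value is missing, non-finite, or out of range."""


class ParseError(TcmnetError):
    """An input file could not be parsed; the message names the line."""


class EmptyInputError(TcmnetError):
    """An operation that needs a non-empty table or graph received an empty one."""


class NoEdgesError(TcmnetError):
    """An operation that needs at least one edge received an edgeless graph."""


class CoverageError(TcmnetError):
    """A partition does not assign every graph node to a community."""


class RegistryError(TcmnetError):
    """An unknown community-detection algorithm name was requested."""


class AnnotationError(TcmnetError):
    """An annotation payload is empty or of the wrong kind."""


class ValidationError(TcmnetError):
    """The coherence validation has no evaluable cluster or no data."""
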