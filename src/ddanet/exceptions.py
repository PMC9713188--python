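"""Exception types shared across the package."""


class DdanetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DdanetError, ValueError):
    """A delimited input file could not be parsed."""


class ConfigError(DdanetError, ValueError):
    """An operation was configured with invalid parameters."""


class GraphError(DdanetError, ValueError):
    """A graph construction or lookup failed."""
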