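"""Exception hierarchy shared across the package."""


class PghmError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PghmError):
    """A sequence file could not be parsed."""


class ConfigurationError(PghmError):
    """Inconsistent or invalid user-supplied configuration."""


class DegenerateInputError(PghmError):
    """Input is structurally valid but statistically degenerate
    (e.g. constant vectors, zero usable reads)."""
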