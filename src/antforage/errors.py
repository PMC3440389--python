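"""Package exception types."""


class AntforageError(Exception):
    """Base class for all package errors."""


class ConfigError(AntforageError):
    """Invalid or inconsistent configuration (geometry, parameters, config file)."""


class ParseError(AntforageError):
    """Malformed input file (bad header, non-numeric cell, ...)."""
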