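"""Exception hierarchy shared by all stages.

``ConfigError`` maps to CLI exit code 1, ``DataError`` (and its subclass
``FormatError``) to exit code 2.
"""


class SnbDecodeError(Exception):
    """Base class for all package errors."""


class ConfigError(SnbDecodeError):
    """Invalid or inconsistent configuration."""


class DataError(SnbDecodeError):
    """Data violates an invariant required by an analysis stage."""


class FormatError(DataError):
    """Malformed on-disk session data."""
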