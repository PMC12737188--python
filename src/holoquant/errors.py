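"""Exception hierarchy shared across the package.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class HoloquantError(Exception):
    """Base class for all package errors."""


class ConfigError(HoloquantError):
    """Invalid configuration or parameters."""


class DataError(HoloquantError):
    """Malformed, inconsistent, or degenerate input data."""
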