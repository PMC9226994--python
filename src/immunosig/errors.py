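"""Exception hierarchy shared across the package.

Exit codes (used by the CLI): 0 success, 2 configuration error,
3 data error, 4 internal error.
"""


class ImmunosigError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ConfigError(ImmunosigError):
    """Invalid configuration value; the message names the offending field."""

    exit_code = 2


class GateDefinitionError(ConfigError):
    """A gate references an unknown marker or has a cyclic parent chain."""


class DataError(ImmunosigError):
    """Invalid or unusable input data."""

    exit_code = 3


class InsufficientDataError(DataError):
    """Too few values to compute the requested statistic."""


class ModelFormatError(DataError):
    """A serialized model file is corrupted or has an unsupported schema."""
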