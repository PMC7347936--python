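"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes so batch callers can tell a
malformed configuration from bad data or a failed estimation.
"""


class MetafaceError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MetafaceError, ValueError):
    """Invalid configuration or parameter values."""


class DataError(MetafaceError, ValueError):
    """Malformed or out-of-contract input data."""


class EstimationError(MetafaceError, RuntimeError):
    """An estimator could not produce a valid result."""


class ContractError(MetafaceError, ValueError):
    """Quantities combined from mismatched provenance."""
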