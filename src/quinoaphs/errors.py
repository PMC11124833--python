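"""Exception hierarchy shared across the pipeline.

Exit codes mirror the CLI contract: 2 configuration, 3 data, 4 numerical.
"""


class QuinoaPHSError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(QuinoaPHSError):
    """Invalid configuration or simulation parameters."""

    exit_code = 2


class DataError(QuinoaPHSError):
    """Malformed, inconsistent or out-of-domain input data."""

    exit_code = 3


class NumericalError(QuinoaPHSError):
    """A numerical procedure failed (rank deficiency, non-convergence)."""

    exit_code = 4


class SimulationError(QuinoaPHSError):
    """The synthetic-data generator cannot satisfy the requested design."""

    exit_code = 2
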