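"""Exception types shared across the package."""


class PosmtdError(Exception):
    """Base class for package errors."""


class ConfigurationError(PosmtdError, ValueError):
    """A task or model configuration is inconsistent or incomplete."""


class DegenerateInputError(PosmtdError, ValueError):
    """An input is degenerate (all-zero row, zero evidence, ...)."""


class InvalidModelError(PosmtdError, ValueError):
    """An operation was applied to the wrong model variant."""


class ImpossibleObservationError(PosmtdError, ValueError):
    """An observation has zero probability under the current belief."""


class SizeError(PosmtdError, ValueError):
    """A brute-force instance is too large to enumerate."""


class SchemaError(PosmtdError, ValueError):
    """Tabular inputs do not match the expected schema."""


class WindowingError(PosmtdError, ValueError):
    """Not enough trials to form the requested early/late windows."""


class SchedulingError(PosmtdError, RuntimeError):
    """The constrained odor scheduler failed after bounded retries."""


class DegenerateClusterError(PosmtdError, ValueError):
    """A waveform cluster has zero variance."""
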