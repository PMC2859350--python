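"""Exception hierarchy shared across the package."""


class TDIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TDIError, ValueError):
    """Invalid user-supplied configuration (column maps, modes, policies)."""


class DataError(TDIError, ValueError):
    """Input data violates a structural invariant."""


class FitError(TDIError, RuntimeError):
    """Model estimation failed (non-convergence, rank deficiency)."""


class NumericError(TDIError, RuntimeError):
    """A numerical routine failed to converge or returned non-finite values."""


class DegenerateDistributionError(NumericError):
    """The paired-difference distribution has zero spread."""
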