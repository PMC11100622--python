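"""Exception hierarchy shared across the package."""


class PyloricError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PyloricError, ValueError):
    """Invalid parameter value (non-positive duration, bad window, ...)."""


class DataError(PyloricError, ValueError):
    """Malformed input data (unsorted spikes, non-positive frequency, ...)."""


class GenerationError(PyloricError, RuntimeError):
    """Synthetic-data generation failed (inconsistent phase table, f <= 0)."""


class FitError(PyloricError, RuntimeError):
    """A fit could not be performed (too few points, missing endpoints)."""


class StatsError(PyloricError, RuntimeError):
    """A statistical routine received an unusable sample."""
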