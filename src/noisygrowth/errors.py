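"""Exception hierarchy shared across the package."""


class NoisyGrowthError(Exception):
    """Base class for all package errors."""


class ParameterError(NoisyGrowthError, ValueError):
    """A model or noise parameter violates its admissible range."""


class InvalidInputError(NoisyGrowthError, ValueError):
    """An operation received input outside its contract (grids, lags, supports)."""


class FitError(NoisyGrowthError, RuntimeError):
    """Parameter recovery from an autocorrelation table failed."""


class EmptyHistogramError(NoisyGrowthError, RuntimeError):
    """No usable replicates remain (all flagged diverged)."""


class UndefinedLimitError(NoisyGrowthError, ValueError):
    """A requested limit does not exist for the given parameters."""
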