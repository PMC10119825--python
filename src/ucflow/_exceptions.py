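"""Exception hierarchy shared across the package."""


class UCFlowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UCFlowError):
    """A user-supplied configuration value is invalid or inconsistent."""


class GenerationError(UCFlowError):
    """The synthetic generator produced an invalid state (e.g. non-positive intensity)."""


class StructuralError(UCFlowError):
    """Input data violate a structural requirement (gaps, duplicates, shape mismatch)."""


class InsufficientHistoryError(UCFlowError):
    """A forecaster was asked for lags/history that the series does not contain."""


class ValidationError(UCFlowError):
    """Loaded data violate the declared schema."""


class DegenerateInputError(UCFlowError):
    """A statistic is undefined on the given input (e.g. zero-variance loss differential)."""
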