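"""Exception hierarchy for the threecb package."""


class ThreeCBError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ThreeCBError, ValueError):
    """Invalid simulation, CAD, or split configuration."""


class CalibrationError(ThreeCBError, ValueError):
    """Calibration design is rank deficient or otherwise unusable."""


class DegenerateModelError(ThreeCBError, ValueError):
    """Attenuation model cannot separate materials (proportional energy rows)."""


class IllConditionedError(ThreeCBError, RuntimeError):
    """Decomposition system condition number exceeds the configured ceiling."""


class InputError(ThreeCBError, ValueError):
    """Malformed operation input (shape mismatch, empty mask, missing columns)."""


class TrainingError(ThreeCBError, ValueError):
    """Classifier training preconditions violated (e.g. single-class labels)."""


class UndefinedMetricError(ThreeCBError, ValueError):
    """A metric that needs both classes was asked of single-class data."""
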