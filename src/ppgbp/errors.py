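"""Exception hierarchy for the ppgbp pipeline.

Every stage raises a subclass of :class:`PPGBPError`, so callers (and the
CLI) can trap pipeline failures without catching unrelated exceptions.
"""


class PPGBPError(Exception):
    """Base class for all ppgbp errors."""


class InvalidConfigError(PPGBPError):
    """A configuration value violates its documented constraints."""


class InvalidProfileError(PPGBPError):
    """A subject profile is missing fields or holds out-of-range values."""


class DegeneratePulseError(PPGBPError):
    """A pulse segment has non-positive amplitude or a zero-length phase."""


class InsufficientPulsesError(PPGBPError):
    """Fewer than the minimum number of valid pulses in an analysis window."""


class MissingModelError(PPGBPError):
    """Lookup of a (gender, age-bin) cell that holds no trained model."""


class EmptyBankError(PPGBPError):
    """Bank training produced no trainable cells at all."""


class FitFailureError(PPGBPError):
    """Every hyperparameter optimisation start failed."""


class SingularKernelError(PPGBPError):
    """Kernel matrix could not be factorised even at the maximum jitter."""


class OutOfRangeAgeError(PPGBPError):
    """Age falls outside the [15, 95) range the bin schemes partition."""


class SchemaError(PPGBPError):
    """A table is missing required columns (or carries unknown ones)."""


class FormatVersionError(PPGBPError):
    """A serialized artifact declares an unsupported format version."""


class SampleSizeError(PPGBPError):
    """A statistic was requested on a sample outside its valid size range."""


class UndefinedCorrelationError(PPGBPError):
    """Correlation requested on a zero-variance input."""


class MissingArtifactError(PPGBPError):
    """A pipeline command needs an upstream artifact that does not exist."""
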