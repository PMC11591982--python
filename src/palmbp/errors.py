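"""Exception hierarchy.

Every error the library raises derives from :class:`PalmBPError` so callers
(and the CLI, which maps them to exit codes) can catch one base class.
"""


class PalmBPError(Exception):
    """Base class for all palmbp errors."""


class InvalidArgumentError(PalmBPError, ValueError):
    """A precondition on an argument was violated."""


class DimensionError(PalmBPError, ValueError):
    """Matrix/vector shapes are not conformable."""


class DegenerateROIError(PalmBPError, ValueError):
    """The palm polygon has (near-)zero area or an empty pixel interior."""


class NoSignalError(PalmBPError, ValueError):
    """Whitening rejected every component: nothing above the noise floor."""


class SingularMatrixError(PalmBPError, ValueError):
    """A matrix required to be full rank is rank deficient."""


class NoBeatsError(PalmBPError, ValueError):
    """No pulse extrema survived detection and interval filtering."""


class InsufficientDataError(PalmBPError, ValueError):
    """Too few calibration records to identify the model."""


class DegenerateFitError(PalmBPError, ValueError):
    """Calibration design is rank deficient (non-identifiable coefficients)."""


class OutOfRangeError(PalmBPError, KeyError):
    """A BMI value falls outside every interval of the parameter table."""


class ConfigurationError(PalmBPError, ValueError):
    """An optimizer or pipeline configuration violates its invariants."""


class ObjectiveError(PalmBPError, ValueError):
    """The objective function returned a non-finite value."""


class CalibrationMismatchError(PalmBPError, ValueError):
    """Calibration parameters were produced under different preprocessing."""
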