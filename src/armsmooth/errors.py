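"""Exception taxonomy for the pipeline.

Every stage raises a specific subclass so callers can distinguish bad
arguments from degenerate data or infeasible optimisation problems.
"""


class ArmsmoothError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ArmsmoothError, ValueError):
    """An argument violates a documented precondition."""


class DegeneratePoseError(ArmsmoothError, ValueError):
    """Sensor geometry makes the subject frame ill-defined (axis ∥ vertical)."""


class NumericDegeneracyError(ArmsmoothError, ArithmeticError):
    """A quantity is ill-defined at this sample (e.g. zero-length projection)."""


class DegenerateTrainingError(ArmsmoothError, ValueError):
    """Classifier training data contain a single class."""


class InfeasibleSegmentationError(ArmsmoothError, RuntimeError):
    """No segmentation satisfies the alternation/duration constraints."""


class UndefinedRatioError(ArmsmoothError, ZeroDivisionError):
    """Jerk ratio requested for two identically-zero jerk values."""


class UndefinedICCError(ArmsmoothError, ArithmeticError):
    """ICC requested on a matrix with zero total variance."""


class DegenerateTestError(ArmsmoothError, ValueError):
    """Paired test requested on all-zero differences."""


class MissingDataError(ArmsmoothError, ValueError):
    """An analysis unit has no usable values."""


class FormatError(ArmsmoothError, ValueError):
    """A file violates the recording CSV dialect."""


class SampleRateMismatchError(FormatError):
    """Recorded sample rate disagrees with the session manifest."""
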