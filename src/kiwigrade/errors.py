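"""Exception hierarchy shared across the package."""


class KiwigradeError(ValueError):
    """Base class for all domain errors raised by kiwigrade."""


class DegenerateImageError(KiwigradeError):
    """Image lacks the structure an operation requires (e.g. a constant image
    has a degenerate histogram and no Otsu threshold)."""


class EmptyForegroundError(KiwigradeError):
    """A binary image contains no white (foreground) pixels."""


class CalibrationError(KiwigradeError):
    """The calibration grid could not be detected, or the pixel/mm ratio is
    invalid."""


class ModelError(KiwigradeError):
    """A linear estimator was evaluated or fitted on invalid inputs."""


class GradingError(KiwigradeError):
    """Grade assignment, confusion accounting, or reclassification received
    inconsistent inputs."""


class SyntheticSpecError(KiwigradeError):
    """A synthetic fruit or population specification is infeasible."""
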