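"""Exception hierarchy shared across the pipeline."""


class FusionError(Exception):
    """Base class for all package errors."""


class FormatError(FusionError):
    """A file could not be read as the requested format."""


class ValidationError(FusionError):
    """An input violates a documented precondition or invariant."""


class RegistrationError(FusionError):
    """Rigid registration could not be performed (e.g. no overlap)."""


class SegmentationError(FusionError):
    """Tissue segmentation failed (degenerate intensity distribution)."""


class FitError(FusionError):
    """A model fit did not converge or had too few data points."""


class CalibrationError(FusionError):
    """A calibration produced a physically impossible value."""


class DomainError(FusionError):
    """An argument lies outside the mathematical domain of an operation."""
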