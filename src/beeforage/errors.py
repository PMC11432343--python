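"""Exception hierarchy shared across the pipeline."""


class BeeforageError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(BeeforageError, ValueError):
    """Invalid scale-bar calibration input."""


class OutOfFrameError(BeeforageError, ValueError):
    """A derived rectangle does not fit inside the frame."""


class ParameterError(BeeforageError, ValueError):
    """An operation received an out-of-domain parameter."""


class ScaleMismatchError(BeeforageError, ValueError):
    """A raster is not on the internal 0-255 HSV channel scale."""


class NoFlowerPixelsError(BeeforageError, ValueError):
    """No in-band pixels were found when at least one was required."""


class EmptyRegionError(BeeforageError, ValueError):
    """A sampling region contained no defined pixels."""


class DesignError(BeeforageError, ValueError):
    """A model design matrix is degenerate (single level / constant column)."""


class TransformationDomainError(BeeforageError, ValueError):
    """A response transformation was applied outside its domain."""

    def __init__(self, message: str, offending_indices=None):
        super().__init__(message)
        self.offending_indices = (
            [] if offending_indices is None else [int(i) for i in offending_indices]
        )
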