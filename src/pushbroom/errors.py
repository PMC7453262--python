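"""Exception hierarchy for the pushbroom pipeline."""


class PushbroomError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(PushbroomError):
    """Spectral calibration could not be established (e.g. non-monotone fit)."""


class BalancingError(PushbroomError):
    """White/dark balancing failed, e.g. the denominator is invalid everywhere."""


class StreamIntegrityError(PushbroomError):
    """A pushbroom frame stream is out of order or incomplete."""


class EstimationError(PushbroomError):
    """Robust model estimation (homography RANSAC) failed."""


class CubeFormatError(PushbroomError):
    """An on-disk cube header or payload is malformed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"{message} (header line {line_number})"
        super().__init__(message)
        self.line_number = line_number
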