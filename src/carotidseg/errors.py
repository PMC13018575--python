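"""Exception hierarchy for carotidseg.

All package-specific failures derive from :class:`CarotidSegError` so callers
can catch one base class at pipeline boundaries.
"""


class CarotidSegError(Exception):
    """Base class for all carotidseg errors."""


class InvalidSpecError(CarotidSegError, ValueError):
    """A phantom specification is inconsistent or out of image bounds."""


class EmptyMaskError(CarotidSegError, ValueError):
    """A binary mask required to be non-empty has no foreground pixels."""


class LabelParseError(CarotidSegError, ValueError):
    """A YOLO-style label file line could not be parsed or validated."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class InvalidPartitionError(CarotidSegError, ValueError):
    """Dataset too small for the requested holdout/fold structure."""


class DetectionMissingError(CarotidSegError, ValueError):
    """No pixel in an overlay passed the blue-box color thresholds."""


class InvalidRegionError(CarotidSegError, ValueError):
    """A scanning region is smaller than the scanning window."""


class NumericalInstabilityError(CarotidSegError, ArithmeticError):
    """Level-set evolution produced non-finite values (diverged)."""
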