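"""Exception hierarchy for the mandown toolkit.

All toolkit-specific failures derive from :class:`MandownError`, so callers
(including the CLI) can distinguish data/contract problems from programming
errors.
"""


class MandownError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MandownError):
    """A text record could not be parsed (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class RangeError(MandownError):
    """A raw sensor count lies outside the representable bit range."""


class AlignmentError(MandownError):
    """Series that must share a common sample grid have mismatched lengths."""


class EmptyInputError(MandownError):
    """An operation received a zero-length recording or series."""


class WindowTooLongError(MandownError):
    """A requested analysis window exceeds the available signal length."""


class InsufficientDataError(MandownError):
    """Too few observations to constrain the requested fit."""


class DegenerateGeometryError(MandownError):
    """Calibration poses do not span enough of the sphere to be invertible."""


class NotStationaryError(MandownError):
    """A segment flagged as stationary shows too much variance."""


class ZeroScaleError(MandownError):
    """A constant sample cannot support a scale (sigma/beta) estimate."""


class FitFailureError(MandownError):
    """Numerical failure of a maximum-likelihood fit."""


class UndefinedRateError(MandownError):
    """PD or PFA requested with no positives (or negatives) present."""


class DegenerateLabelsError(MandownError):
    """Training requires both classes; only one is present."""
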