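"""Exception and warning types shared across the pipeline."""


class HtedaError(Exception):
    """Base class for all package errors."""


class CalibrationError(HtedaError):
    """Raised when a reference/calibration relationship is unusable
    (e.g. reference maximum not above solvent background, non-positive
    slope, degenerate calibrant set)."""


class FitFailureError(HtedaError):
    """Raised when a dose-response fit cannot be performed or does not
    converge. Carries diagnostics in ``.details`` when available."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class StageError(HtedaError):
    """Pipeline stage failure; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


class DegenerateSpreadWarning(UserWarning):
    """All fractions identical (MAD = 0): no activity can be called."""


class BelowRangeWarning(UserWarning):
    """Quantification below the lowest calibration standard (extrapolated)."""
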