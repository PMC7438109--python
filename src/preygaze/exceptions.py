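"""Exception hierarchy for the preygaze pipeline."""


class PreygazeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PreygazeError, ValueError):
    """Raised for malformed input files (bad headers, missing channels)."""


class FitError(PreygazeError, RuntimeError):
    """Raised when a geometric fit is degenerate or underdetermined."""


class CalibrationError(PreygazeError, RuntimeError):
    """Raised when eye-camera calibration cannot be estimated."""


class AnalysisError(PreygazeError, RuntimeError):
    """Raised when a statistic is requested on empty or degenerate data."""
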