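"""Exception types shared across the package."""


class EogSemgError(Exception):
    """Base class for all package-specific errors."""


class InvalidScheduleError(EogSemgError, ValueError):
    """Event schedule violates ordering / overlap constraints."""


class RecordingParseError(EogSemgError, ValueError):
    """A recording or ground-truth file could not be parsed."""


class CalibrationError(EogSemgError, ValueError):
    """Per-user threshold calibration is infeasible on the given recording."""


class InvalidEpisodeError(EogSemgError, ValueError):
    """An sEMG episode has no active channel and cannot be classified."""


class InsufficientDataError(EogSemgError, ValueError):
    """Recording too short for the requested analysis."""
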