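"""Exception hierarchy. User-facing errors derive from ShikscreenError."""


class ShikscreenError(Exception):
    """Base class for all user-facing errors raised by this package."""


class NoMatchStatesError(ShikscreenError):
    """Alignment yields no match states (all columns are >50% gaps)."""


class CalibrationError(ShikscreenError):
    """E-value calibration failed (degenerate score distribution)."""


class NotCalibratedError(ShikscreenError):
    """E-value requested from an uncalibrated profile."""


class PathwayConfigError(ShikscreenError):
    """Invalid pathway definition document."""


class CohortError(ShikscreenError):
    """Inconsistent cohort inputs (e.g. calls without metadata)."""


class ConcordanceError(ShikscreenError):
    """Concordance comparison impossible (e.g. no shared genomes)."""
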