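"""Exception hierarchy for the pipeline.

All pipeline-specific failures derive from :class:`HdtCardioError` so callers
can catch the whole family; subclasses distinguish recoverable data-quality
failures from configuration and state errors.
"""


class HdtCardioError(Exception):
    """Base class for all pipeline errors."""


class UnprocessableSignalError(HdtCardioError):
    """Raised when a waveform is flat, non-finite or otherwise unusable."""


class InsufficientDataError(HdtCardioError):
    """Raised when a recording is too short or has too few beats."""


class QualityFailureError(HdtCardioError):
    """Raised when too large a fraction of beats is flagged as artifact."""


class SpectralStateError(HdtCardioError):
    """Raised on invalid raw/smoothed state transitions of a spectrum."""


class CoverageError(HdtCardioError):
    """Raised when a frequency grid does not cover a requested band."""


class UndefinedRateError(HdtCardioError):
    """Raised when the EDR spectrum carries no in-band power."""


class DegenerateSeriesError(HdtCardioError):
    """Raised on zero-variance input where a scaling exponent is undefined."""


class DomainError(HdtCardioError, ValueError):
    """Raised on out-of-domain numeric input (non-positive value, p outside
    [0, 1], baseline <= 0, ...)."""


class MissingPairError(HdtCardioError):
    """Raised when a before/after or baseline pair is incomplete."""


class InfeasibleConfigError(HdtCardioError):
    """Raised when a generator configuration cannot produce a valid signal."""


class DesignError(HdtCardioError):
    """Raised on a singular fixed-effect design (empty factor cell)."""


class EstimationError(HdtCardioError):
    """Raised when REML estimation fails to converge."""
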