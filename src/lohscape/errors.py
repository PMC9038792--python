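"""Exception hierarchy shared across the package."""


class LohscapeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LohscapeError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(LohscapeError):
    """A tabular input is missing columns or contains malformed rows."""


class MissingReferenceError(LohscapeError):
    """A tumor SNP site has no matching process-matched reference depth."""


class InsufficientDataError(LohscapeError):
    """Too few observations to run the requested estimator."""


class NoInflectionError(LohscapeError):
    """The ranked curve has no detectable inflection (e.g. a linear ramp)."""


class UnestimableError(LohscapeError):
    """Purity/ploidy cannot be estimated from the available segments."""


class QCFailureError(LohscapeError):
    """Sample failed quality control; carries the machine-readable reason."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or f"sample failed QC: {reason}")


class UndefinedScoreError(LohscapeError):
    """Percent gLOH is undefined (zero non-excluded genome length)."""


class NoEventsError(LohscapeError):
    """Survival data contain no events; estimator undefined."""


class SingleGroupError(LohscapeError):
    """Dichotomization produced a single group (all values identical)."""


class SingularDesignError(LohscapeError):
    """Design matrix is rank deficient even after dropping collinear columns."""


class ConvergenceError(LohscapeError):
    """Iterative fit failed to converge; message carries diagnostics."""
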