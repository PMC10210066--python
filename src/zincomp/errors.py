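"""Exception hierarchy for zincomp.

Validation of user-supplied values raises :class:`ValidationError` (a
``ValueError``), so callers can catch one type for bad inputs.  Failures of
the numerical machinery (non-convergence, no physical root, unusable data)
raise dedicated subclasses of :class:`ZincompError`.
"""


class ZincompError(Exception):
    """Base class for zincomp-specific failures."""


class ValidationError(ZincompError, ValueError):
    """An input violates a documented precondition."""


class SolverError(ZincompError):
    """The speciation solver failed to converge.

    Carries the last mass-balance residual so callers can decide whether the
    answer is still usable.
    """

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


class ModelInconsistencyError(ZincompError):
    """No root exists in the physical interval of an exchange model."""


class NoTransferError(ZincompError):
    """An observation shows no transferred metal; the estimator is undefined."""


class OutOfRegimeError(ZincompError):
    """Transferred metal outside the single-event regime of an estimator."""


class ProbeSaturationError(ZincompError):
    """Fluorescence at or above Fmax; free metal is not determinable."""


class NoTransitionError(ZincompError):
    """Isotherm data show no transition above the noise floor."""


class FitFailureError(ZincompError):
    """A nonlinear fit failed to converge or has no finite covariance."""


class ConfigError(ZincompError):
    """A run configuration failed schema validation."""
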