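"""Exception hierarchy shared across the pipeline stages."""


class PainLimitsError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PainLimitsError, ValueError):
    """A precondition on an argument was violated."""


class SimulationLimitError(PainLimitsError):
    """A simulated protocol could not reach the requested state."""


class NoContactError(PainLimitsError):
    """No contact onset could be detected in a force signal."""


class MissingEventError(PainLimitsError):
    """An algometer signal lacks the switch-press event index."""


class MalformedSeriesError(PainLimitsError):
    """A staircase series violates the protocol contract."""


class UnderdeterminedInterpolationError(PainLimitsError):
    """A film contour has too few covered sensels to interpolate."""


class CalibrationImpossibleError(PainLimitsError):
    """A zero pressure frame cannot be scaled to a positive force."""


class LikelihoodDegenerateError(PainLimitsError):
    """The censored-data likelihood is not finite at these parameters."""


class FitFailureError(PainLimitsError):
    """Maximum-likelihood estimation did not converge."""


class IdentifiabilityError(PainLimitsError):
    """The requested model is not identifiable from the sample."""


class DegenerateTestError(PainLimitsError):
    """A Wald test cannot be formed (zero or invalid standard error)."""


class ConfigurationError(PainLimitsError):
    """A pipeline configuration is inconsistent."""
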