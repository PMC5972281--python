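"""Exception hierarchy for cfasim."""


class CFASimError(Exception):
    """Base class for all cfasim errors."""


class InvalidModelError(CFASimError):
    """Population or fitted model dimensions/values are inconsistent."""


class DegenerateDataError(CFASimError):
    """Sample is too small or collinear for the requested computation."""


class InvalidThresholdError(CFASimError):
    """Discretization thresholds are not strictly ascending."""


class EstimationInputError(CFASimError):
    """Moment matrix unsuitable for estimation (singular, wrong shape...)."""


class SaturatedModelError(CFASimError):
    """Fit statistics requested for a model with no degrees of freedom."""


class CaseLookupError(CFASimError, KeyError):
    """Requested CASE id is not present in the study results."""
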