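"""Exception hierarchy.

All package errors derive from :class:`FcnflowError`; validation failures on
input tables derive from :class:`ValidationError` so callers can distinguish
bad data from bad usage.
"""


class FcnflowError(Exception):
    """Base class for all fcnflow errors."""


class ValidationError(FcnflowError):
    """An input table violated a structural invariant."""


class DuplicateReachIdError(ValidationError):
    """Two rows of a reach table share a reach_id."""


class DanglingDownstreamError(ValidationError):
    """A downstream_id does not resolve to any reach in the table."""


class CycleError(ValidationError):
    """Following downstream pointers revisits a reach."""


class NonPositiveValueError(ValidationError):
    """A length or drainage area is zero or negative."""


class InvalidCategoryError(ValidationError):
    """A categorical field holds a value outside its enumeration."""


class EmptyNetworkError(FcnflowError):
    """An operation would leave (or received) a network with no reaches."""


class UnknownReachError(FcnflowError):
    """A reach_id was requested that is not in the network."""


class UnknownBarrierReachError(FcnflowError):
    """A barrier references a reach_id absent from the network."""


class MissingAttributeError(FcnflowError):
    """A required reach attribute is missing and no fallback is configured."""


class ShapeMismatchError(FcnflowError):
    """Two community matrices disagree in shape or alignment."""


class TooFewSitesError(FcnflowError):
    """Not enough sites for the requested statistical procedure."""


class NoPredictorsError(FcnflowError):
    """Predictor screening removed every candidate."""


class UndefinedChangeError(FcnflowError):
    """Percent change from a zero baseline is undefined."""
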