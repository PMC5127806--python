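"""Exception hierarchy for trflab.

All package-specific failures derive from :class:`TRFError` so callers (and
the CLI) can catch one base class.
"""


class TRFError(Exception):
    """Base class for all trflab errors."""


class InvalidArgumentError(TRFError, ValueError):
    """An argument violates a precondition (non-finite data, length
    mismatch, bad sampling rate, ...)."""


class IllPosedDesignError(TRFError, ValueError):
    """The lagged design has at least as many columns as time samples, so
    the least-squares problem is under-determined."""


class SingularDesignError(TRFError, ValueError):
    """The (possibly regularized) normal equations are singular; typically
    raised at lambda = 0 on rank-deficient designs."""


class InvalidPenaltyError(TRFError, ValueError):
    """The quadratic smoothness penalty was requested for a design with
    more than one feature per lag, where it would smear across features."""


class UndefinedMetricError(TRFError, ValueError):
    """A metric (e.g. lambda selection) is undefined for all candidates."""


class AliasingError(TRFError, ValueError):
    """A filterbank band exceeds the Nyquist frequency of the signal."""
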