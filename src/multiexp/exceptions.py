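"""Exception hierarchy for multiexp."""


class MultiexpError(Exception):
    """Base class for all multiexp errors."""


class SignalFormatError(MultiexpError, ValueError):
    """A signal file violates the two-column plain-text dialect."""


class IllConditionedBasisError(MultiexpError, ValueError):
    """The Gram matrix of the exponential basis is numerically singular."""


class FitFeasibilityError(MultiexpError, RuntimeError):
    """No decomposition with strictly positive weights exists for the signal."""
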