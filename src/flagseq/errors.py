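"""Exception types shared across flagseq modules."""


class FlagseqError(Exception):
    """Base class for all flagseq errors."""


class ParameterError(FlagseqError, ValueError):
    """An argument violates a documented precondition."""


class EncodingError(FlagseqError):
    """Reverse translation cannot satisfy the forbidden-motif constraints.

    Carries the 0-based nucleotide position of the offending motif when known.
    """

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class CapacityError(FlagseqError):
    """A barcode code of the requested size/distance cannot be constructed."""


class FitError(FlagseqError):
    """Null-model fitting failed (e.g. too few observations everywhere)."""


class InsufficientDataError(FlagseqError):
    """A statistical comparison was requested on too few observations."""


class UnclassifiableError(FlagseqError):
    """TLR5 readouts fall in a quadrant with no defined flagellin class."""
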