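"""Named exceptions raised across the pipeline."""


class MTENMError(Exception):
    """Base class for all package errors."""


class MissingMonthError(MTENMError, ValueError):
    """A non-fossil record lacks a collection month."""


class EmptyAgeMassError(MTENMError, ValueError):
    """A fossil record has no calibrated-age probability mass."""


class AllMaskedError(MTENMError, ValueError):
    """Every cell in an extraction neighbourhood is land."""


class ZeroWeightError(MTENMError, ValueError):
    """Training weights are all zero (or negative)."""


class EmptyInputError(MTENMError, ValueError):
    """A metric received an empty presence or background set."""


class DegenerateSuitabilityError(MTENMError, ValueError):
    """Suitability values are constant; rank-based metrics are undefined."""


class DegenerateResponseError(MTENMError, ValueError):
    """Bias-model response values are all equal; nothing to fit."""


class ConvergenceError(MTENMError, RuntimeError):
    """An iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ZeroReferenceError(MTENMError, ValueError):
    """Percent change requested against a non-positive reference."""
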