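"""Exception hierarchy for the MR pipeline."""


class BidirMRError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(BidirMRError, ValueError):
    """A configuration value is outside its admissible domain."""


class InvalidInputError(BidirMRError, ValueError):
    """Input data violate a precondition (empty matrix, unsorted positions, ...)."""


class SingularDesignError(BidirMRError):
    """Design matrix is rank deficient."""


class SeparationError(BidirMRError):
    """Complete or quasi-complete separation in a logistic fit."""


class UndefinedCorrelationError(BidirMRError):
    """Correlation requested for a constant vector or too few complete pairs."""


class HarmonizationError(BidirMRError):
    """Exposure and outcome summary statistics cannot be aligned."""


class InsufficientInstrumentsError(BidirMRError):
    """An estimator was called with fewer instruments than it requires."""


class NoInstrumentsError(BidirMRError):
    """Instrument discovery/screening left an empty set; MR cannot proceed."""


class UnitError(BidirMRError):
    """A scale transform was requested on the wrong estimand scale."""
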