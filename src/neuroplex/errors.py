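"""Exception types raised across the package."""


class NeuroplexError(ValueError):
    """Base class for all package-specific errors."""


class NoAlphaPeakError(NeuroplexError):
    """No local spectral peak found inside the alpha search range."""


class TooSparseError(NeuroplexError):
    """A weighted matrix has fewer nonzero entries than the target edge count."""


class UnderdeterminedEstimateError(NeuroplexError):
    """A record is too short for the requested estimator configuration."""


class LabelMismatchError(NeuroplexError):
    """Row and column labels of a matrix file disagree."""
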