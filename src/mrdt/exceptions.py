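"""Exception hierarchy for mrdt."""


class MRDTError(Exception):
    """Base class for all mrdt errors."""


class FormatError(MRDTError):
    """A file does not conform to the expected delimited-text layout."""


class ValidationError(MRDTError):
    """Values violate a domain invariant (alleles, SEs, correlation range, ...)."""


class HarmonizationError(MRDTError):
    """Exposure and outcome tables cannot be aligned (e.g. no shared SNPs)."""


class EstimationError(MRDTError):
    """An estimator's preconditions are not met (too few SNPs, null
    instrument, singular weight matrix, ...)."""
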