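"""Typed exceptions raised by rarescape readers and analyses."""


class RarescapeError(Exception):
    """Base class for all rarescape errors."""


class FormatError(RarescapeError):
    """Malformed input file (bad dialect, non-numeric cell, wrong shape)."""


class NegativeCountError(FormatError):
    """A read count is negative or non-integral."""


class DuplicateIdError(FormatError):
    """Duplicate sample/OTU/tip identifier."""


class MissingMetadataError(RarescapeError):
    """A sample present in the count table has no metadata row."""


class UnknownModalityError(RarescapeError):
    """Categorical trait value not in the declared modality order."""


class EmptyInputError(RarescapeError):
    """An operation received an empty table, window or fraction."""


class InsufficientDataError(RarescapeError):
    """Too few samples/OTUs to run the requested analysis."""


class ParameterError(RarescapeError):
    """Invalid parameter combination (e.g. window < step)."""


class SaturationError(RarescapeError):
    """Sequence divergence beyond the model's domain (p >= 0.75)."""


class ClassificationError(RarescapeError):
    """Non-finite statistic passed to the assembly-process classifier."""


class EmptySummaryError(RarescapeError):
    """No classified pairs available to summarize."""
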