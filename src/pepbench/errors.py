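"""Exception hierarchy shared across the package."""


class PepbenchError(Exception):
    """Base class for all package errors."""


class ValidationError(PepbenchError):
    """Input violates a documented contract (bad symbol, bad shape, bad label)."""


class EmptyInputError(ValidationError):
    """An operation received an empty dataset or file."""


class LabelingError(ValidationError):
    """A FASTA record could not be resolved to a binary class label."""


class InvalidParameterError(ValidationError):
    """A parameter lies outside its declared domain."""


class RegistryError(InvalidParameterError):
    """Unknown encoding group or parameter name."""


class AlignmentRequiredError(ValidationError):
    """A per-residue encoding was given ragged, unaligned sequences."""


class InvalidIndexError(InvalidParameterError):
    """An amino-acid index is unusable (e.g. zero variance)."""


class EmptyEncodingError(PepbenchError):
    """Every record of a dataset was dropped by an encoder's length rule."""


class UndefinedStatisticError(PepbenchError):
    """A statistic is mathematically undefined on the given input."""


class BackendError(PepbenchError):
    """The pluggable sequence-search backend failed."""
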