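"""Exception hierarchy for protacsol.

Every error raised on bad scientific input derives from
:class:`ProtacsolError`, so callers can catch one base class at pipeline
boundaries while tests can assert on the precise failure mode.
"""


class ProtacsolError(Exception):
    """Base class for all protacsol errors."""


class SchemaError(ProtacsolError):
    """A tabular input is missing a required column or has a malformed layout."""


class StructureError(ProtacsolError):
    """A SMILES/SDF record does not parse to a valid connection table."""


class ReferenceError_(ProtacsolError):
    """An identifier refers to a compound that is not in the dataset."""


class UndefinedIndexError(ProtacsolError):
    """A topological index is undefined for this graph (too few atoms/paths)."""


class NegativeRetentionError(ProtacsolError):
    """Retention time earlier than the dead time."""


class DeadTimeError(ProtacsolError):
    """Non-positive column dead time."""


class UndefinedLogError(ProtacsolError):
    """log of a non-positive capacity factor requested."""


class InsufficientDataError(ProtacsolError):
    """Fewer observations than the operation requires."""


class DegenerateDesignError(ProtacsolError):
    """A regression design matrix without variance (e.g. constant x)."""


class UnusableCurveError(ProtacsolError):
    """A calibration curve whose slope is zero cannot be inverted."""


class DomainError(ProtacsolError):
    """A numeric argument outside the physically meaningful domain."""


class ParameterizationError(ProtacsolError):
    """A required per-element parameter (e.g. vdW radius) is unknown."""
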