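"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`CytobenchError`
so the CLI can map them onto non-zero exit codes uniformly.
"""


class CytobenchError(Exception):
    """Base class for all package errors."""


class FCSParseError(CytobenchError):
    """Malformed FCS file (header, text segment or data segment)."""


class EmptyDataError(CytobenchError):
    """An FCS file or frame contains zero events."""


class MetadataError(CytobenchError):
    """Sample-annotation CSV violates the required schema or cardinality."""


class ArgumentError(CytobenchError):
    """Invalid argument to a library operation."""


class TechniqueMismatchError(CytobenchError):
    """FC and MC frames mixed, or a method applied to the wrong technique."""


class UnknownMethodError(CytobenchError):
    """Workflow string names a method absent from the registry."""


class StepMismatchError(CytobenchError):
    """Workflow token sits in the wrong step slot."""


class CompensationError(CytobenchError):
    """Missing or singular spillover information."""


class TransformError(CytobenchError):
    """Per-channel transformation could not be estimated or applied."""


class NormalizationError(CytobenchError):
    """Cross-sample normalization precondition violated."""


class SignalCleanError(CytobenchError):
    """Time channel missing or cleaning would remove too many events."""


class EvaluationError(CytobenchError):
    """A criterion could not be computed on the given data."""
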