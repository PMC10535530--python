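"""Exception hierarchy for the palscreen pipeline."""


class PalscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PalscreenError, ValueError):
    """A file or record violates the expected dialect."""


class NodeKindConflictError(PalscreenError, ValueError):
    """One node id declared with two different kinds."""


class NodeLookupError(PalscreenError, KeyError):
    """A referenced node id is not in the graph."""


class AnnotationStateError(PalscreenError, RuntimeError):
    """An operation requires ARR-annotated pathways but got unannotated ones."""


class NormalizationError(PalscreenError, ValueError):
    """Count normalization cannot proceed (no usable reference genes)."""


class UndefinedPALError(PalscreenError, ZeroDivisionError):
    """Pathway activation level has a zero denominator (no covered nonzero-ARR member)."""


class StratumError(PalscreenError, ValueError):
    """A screening stratum violates minimum group-size preconditions."""


class CoxConvergenceError(PalscreenError, RuntimeError):
    """Partial-likelihood maximization did not converge (e.g. monotone likelihood)."""


class ConfigError(PalscreenError, ValueError):
    """A synthetic-data or run configuration is internally inconsistent."""
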