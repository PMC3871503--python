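"""Exception hierarchy shared across the package."""


class PadRbfError(Exception):
    """Base class for all padrbf errors."""


class InvalidRecordError(PadRbfError, ValueError):
    """A patient record violates the schema (bad range, missing field, unknown token)."""


class CohortSpecError(PadRbfError, ValueError):
    """A synthetic-cohort specification is infeasible or inconsistent."""


class InfeasibleKError(PadRbfError, ValueError):
    """Requested more clusters than there are distinct samples."""


class DegenerateGeometryError(PadRbfError, ValueError):
    """Center geometry does not admit the requested quantity (e.g. spread of coincident centers)."""


class UndefinedROCError(PadRbfError, ValueError):
    """ROC analysis requested on single-class input."""


class NotFittedError(PadRbfError, RuntimeError):
    """Operation requires a fitted network."""
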