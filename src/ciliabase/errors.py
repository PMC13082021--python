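"""Exception hierarchy shared across the package."""


class CiliabaseError(Exception):
    """Base class for all ciliabase errors."""


class InvalidModelError(CiliabaseError):
    """A synthetic-data model violates its invariants."""


class InvalidTraceError(CiliabaseError):
    """A filament trace is degenerate (fewer than two distinct points)."""


class InsufficientGeometryError(CiliabaseError):
    """Not enough filaments/points to define the requested geometry."""


class DegenerateGeometryError(CiliabaseError):
    """Point cloud is collinear/coincident; a surface fit is undefined."""


class NonContiguousLabelsError(CiliabaseError):
    """Zone labels are not contiguous along arc length; run enforce_ordering first."""


class UnlabeledParticleError(CiliabaseError):
    """An operation requiring class labels met an unlabeled particle."""


class SchemaError(CiliabaseError):
    """A tabular input is missing required columns or has malformed values."""


class NoGapError(CiliabaseError):
    """An intensity profile has fewer than two signal-support intervals."""


class GenerationError(CiliabaseError):
    """A synthetic generator cannot satisfy its constraints."""


class ConfigError(CiliabaseError):
    """A run configuration contains unknown keys or invalid values."""
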