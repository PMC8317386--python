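"""Exception hierarchy shared across the pipeline."""


class CentroquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CentroquantError):
    """A file could not be read as the expected on-disk format."""


class SchemaError(CentroquantError):
    """A table or stack is missing a required column/channel."""


class PlacementError(CentroquantError):
    """Synthetic objects could not be placed under the configured constraints."""


class DomainError(CentroquantError, ValueError):
    """An input violates a mathematical precondition (negative count, empty sample...)."""


class UndefinedValueError(DomainError):
    """A ratio or measurement is undefined (zero volume, zero signal, all-zero ROI)."""


class DegenerateTableError(DomainError):
    """A contingency table has a zero margin and cannot be tested."""
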