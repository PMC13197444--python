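"""Exception hierarchy shared across the pipeline stages."""


class DualPetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DualPetError, ValueError):
    """A configuration field is invalid; the message names the field."""


class FormatError(DualPetError, ValueError):
    """An input file exists but is not in the expected format."""


class GridMismatchError(DualPetError, ValueError):
    """Two volumes that must share a voxel grid do not."""


class DomainError(DualPetError, ValueError):
    """An argument violates a precondition of an operation."""


class PlacementError(DomainError):
    """A lesion center falls outside the voxel grid."""


class StatsError(DualPetError, ValueError):
    """A statistical routine received degenerate input."""


class StratificationError(StatsError):
    """A class has too few members for the requested stratified folds."""
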