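"""Exception hierarchy.

Errors are grouped by contract: geometry/model construction, filtering and
detection, decomposition, inverse solutions, and configuration.
"""


class IrritmapError(Exception):
    """Base class for all package errors."""


class GeometryError(IrritmapError):
    """Invalid head geometry (open meshes, sources outside compartments...)."""


class ModelError(IrritmapError):
    """Invalid forward-model parameters (radii, conductivities...)."""


class ReferenceError_(IrritmapError):
    """Average-reference contract violation (e.g. a single electrode)."""


class FilterError(IrritmapError):
    """Band edges outside (0, Nyquist) or otherwise unrealizable filters."""


class TemplateError(IrritmapError):
    """IED template duration outside its kind's band."""


class ConfigError(IrritmapError):
    """Invalid simulation or pipeline configuration."""


class EpochError(IrritmapError):
    """Epoch window incompatible with the recording."""


class DecompositionError(IrritmapError):
    """Degenerate tensor decomposition (rank-deficient factors...)."""


class AssignmentError_(IrritmapError):
    """Invalid cluster assignment (empty cluster, label out of range)."""


class ContractError(IrritmapError):
    """Mismatched inputs between pipeline stages (channels, referencing)."""


class RegularizationError(IrritmapError):
    """Singular standardization block in the inverse solution."""


class SelectionError(IrritmapError):
    """Target/control selection failure (no contralateral partner...)."""


class LookupError_(IrritmapError):
    """Unknown parcel identifier."""


class LatencyError(IrritmapError):
    """Flat epoch: no analysis latency can be defined."""
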