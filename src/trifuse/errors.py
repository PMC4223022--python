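"""Exception hierarchy for trifuse.

All trifuse errors derive from :class:`TrifuseError` so callers (and the CLI)
can catch package failures without masking programming errors.
"""


class TrifuseError(Exception):
    """Base class for all trifuse errors."""


class GeometryError(TrifuseError):
    """Grids or geometric objects are incompatible (shape/spacing/origin mismatch,
    degenerate normals, ...)."""


class TransformError(TrifuseError):
    """A rigid transform is invalid (non-orthonormal rotation, wrong shape)."""


class ParameterError(TrifuseError):
    """A scalar parameter is out of its valid range (window width, transparency, ...)."""


class DimensionalityError(TrifuseError):
    """An image is not a 3D scalar volume."""


class EmptyInputError(TrifuseError):
    """An operation that needs a nonempty mask/mesh received an empty one."""


class ProtocolError(TrifuseError):
    """A delineation-protocol precondition is violated (e.g. a 'kept part' that is
    not a subset of the region it must come from)."""


class InputError(TrifuseError):
    """Statistical input is unusable (too few values, mismatched labels, ...)."""


class SimulationError(TrifuseError):
    """A synthetic-data simulation produced a degenerate result (e.g. an observer
    mask perturbed into emptiness)."""
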