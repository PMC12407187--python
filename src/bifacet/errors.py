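"""Exception hierarchy shared across the package."""


class BifacetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BifacetError):
    """A coordinate or table file could not be parsed under the named standard."""


class ValidationError(BifacetError):
    """An object violates a structural invariant (missing CA, bad rotation, ...)."""


class CapacityError(BifacetError):
    """A format limit was exceeded (e.g. >62 chains in strict PDB)."""


class ConditioningError(BifacetError):
    """A numerical problem is degenerate (too few or collinear points)."""


class AxisMismatchError(BifacetError):
    """A rotation's axis is not parallel to the requested reference axis."""


class PartitionError(BifacetError):
    """Chains cannot be partitioned as a symmetry order requires."""
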