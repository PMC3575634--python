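"""Exception types shared across the pipeline."""


class FemfitError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(FemfitError, ValueError):
    """An implant specification violates its invariants."""


class MeshIntegrityError(FemfitError, ValueError):
    """A surface mesh is not watertight / manifold where it must be."""


class SchemaError(FemfitError, ValueError):
    """A landmark or config file does not match the documented schema."""


class GeometryError(FemfitError, ValueError):
    """A geometric construction or query is infeasible."""


class DegenerateFrameError(GeometryError):
    """Landmarks do not define a well-conditioned anatomical frame."""


class ConfigError(FemfitError, ValueError):
    """A run configuration is invalid."""


class InsufficientDataError(FemfitError, ValueError):
    """Too few observations for the requested statistic."""
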