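"""Exception hierarchy for the blebpoint pipeline.

Each pipeline stage raises a distinct subclass so the CLI can map failures
to stage-specific exit codes and remediation hints.
"""


class BlebpointError(Exception):
    """Base class for all blebpoint errors."""


class FormatError(BlebpointError):
    """A file could not be parsed in the requested format."""


class TopologyError(BlebpointError):
    """Mesh topology is unsupported (non-triangular faces, broken faces...)."""


class AlignmentError(BlebpointError):
    """A field does not align with the mesh (vertex-count mismatch)."""


class OrderingError(BlebpointError):
    """Time stamps of a field series are not strictly increasing."""


class EmptyInletError(BlebpointError):
    """No mesh vertices lie within tolerance of the inlet plane."""


class DegenerateInletError(BlebpointError):
    """Inlet averaging weights sum to zero."""


class EmptyDomainError(BlebpointError):
    """The requested sampling subregion has no faces / zero area."""


class LabellingError(BlebpointError):
    """Sampled region is missing bleb/nonbleb vertex labels."""


class IntegrityError(BlebpointError):
    """A sample point references an invalid anchor face."""


class NormalizationError(BlebpointError):
    """Normalization reference is non-positive."""


class RangeError(BlebpointError):
    """The waveform does not cover the requested cardiac cycle."""


class InsufficientDataError(BlebpointError):
    """Too few time samples for a cycle integral."""


class UndefinedOSIError(BlebpointError):
    """OSI is undefined (identically zero WSS over the cycle)."""


class AssignmentError(BlebpointError):
    """Two divergence centers map to the same sample point."""


class ResolutionError(BlebpointError):
    """Synthetic mesh resolution too coarse for the requested feature."""


class PlacementError(BlebpointError):
    """A planted feature falls outside its admissible region."""


class ConfigError(BlebpointError):
    """Invalid or contradictory run configuration."""
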