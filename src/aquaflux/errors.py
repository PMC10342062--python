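"""Exception types raised across the package."""


class AquafluxError(Exception):
    """Base class for package-specific errors."""


class TopologyMismatchError(AquafluxError):
    """Topology and coordinate sources disagree on atom count."""


class TrajectoryFormatError(AquafluxError):
    """A trajectory or topology file could not be parsed."""


class SelectionError(AquafluxError):
    """An atom selection is empty or malformed."""


class UndersamplingError(AquafluxError):
    """Frame stride too coarse: a per-frame displacement reaches half the box."""


class StabilityError(AquafluxError):
    """Brownian integrator step too large for the potential gradient."""


class SpecificationError(AquafluxError):
    """A synthetic-data specification violates its invariants."""


class InsufficientDataError(AquafluxError):
    """A time series is too short for the requested fit."""


class UndefinedCorrelationError(AquafluxError):
    """Correlation requested between series with zero variance."""
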