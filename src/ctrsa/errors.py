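"""Exception hierarchy for the ctrsa package."""


class CtrsaError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(CtrsaError):
    """A volume file could not be read or written in a supported format."""


class ValidationError(CtrsaError):
    """A domain object violates one of its invariants."""


class ConfigurationError(CtrsaError):
    """A simulator or study configuration is inconsistent."""


class GeometryError(CtrsaError):
    """A geometric precondition failed (marker outside FOV, marker behind focus, ...)."""


class DetectionError(CtrsaError):
    """Bead detection produced no usable candidates."""


class RefinementError(CtrsaError):
    """Centroid refinement found no signal in its window."""


class LabellingError(CtrsaError):
    """Detected candidates could not be matched unambiguously to a template."""


class DegenerateConfigurationError(CtrsaError):
    """Marker configuration is too degenerate for a rigid-body fit."""


class GimbalLockError(CtrsaError):
    """Cardan decomposition requested too close to |ry| = 90 degrees."""


class ReconstructionError(CtrsaError):
    """Stereo ray reconstruction is ill-conditioned."""


class ManifestError(CtrsaError):
    """A study manifest is missing required positions/series."""


class PairingError(CtrsaError):
    """Two migration lists cannot be paired for an accuracy comparison."""


class InsufficientDataError(CtrsaError):
    """Too few observations for the requested statistic."""
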