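"""Exception hierarchy for the sinuct pipeline."""


class SinuctError(Exception):
    """Base class for all sinuct-specific errors."""


class PlacementError(SinuctError):
    """Lumen packing failed: the requested number of primitives could not be
    placed under the grade's contact constraints within the retry budget."""


class UnknownLabelError(SinuctError, KeyError):
    """A label id was requested that does not exist in the label volume."""


class GeometryError(SinuctError):
    """Acquisition geometry is inconsistent with the phantom (e.g. detector
    pixel pitch differs from the phantom voxel size and resampling is off)."""


class ValidationError(SinuctError, ValueError):
    """Input array failed validation (non-finite values, wrong shape...)."""


class ConfigurationError(SinuctError, ValueError):
    """A configuration value is inconsistent (e.g. Poisson noise requested
    with non-positive flat-field counts)."""


class CorrectionError(SinuctError):
    """Flat/dark correction impossible (flat and dark fields coincide)."""


class NoContrastError(SinuctError):
    """Segmentation input has a degenerate (single-valued) histogram."""


class UnsupportedGeometryError(SinuctError):
    """Reconstruction was asked for a geometry it does not support
    (non-uniform angular spacing, angular span >= 360 degrees)."""


class MatchingError(SinuctError):
    """Recovered labels share no voxel overlap with ground-truth labels."""
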