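"""Exception types shared across the pipeline."""


class NeolesionError(Exception):
    """Base class for pipeline errors."""


class DimensionalityError(NeolesionError):
    """Image is not a 3D volume."""


class LayoutError(NeolesionError):
    """Patient directory does not follow the expected file layout."""


class RegistrationError(NeolesionError):
    """Baseline and follow-up grids differ; inputs must be co-registered."""


class GridMismatchError(NeolesionError):
    """Two masks/volumes that must share a grid do not."""


class MaskValueError(NeolesionError):
    """Mask contains values outside {0, 1}."""


class DegenerateInputError(NeolesionError):
    """Input lacks the foreground needed for the operation."""


class CanvasOverflowError(NeolesionError):
    """A slice exceeds the padding canvas."""


class MissingLabelError(NeolesionError):
    """Operation requires labelled slice records."""


class CompletenessError(NeolesionError):
    """A per-slice prediction set does not cover every slice index."""


class ConfigurationError(NeolesionError):
    """Invalid network or pipeline configuration."""


class PlacementError(NeolesionError):
    """A synthetic lesion could not be placed inside the brain."""
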