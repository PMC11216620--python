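"""Exception hierarchy shared across the pipeline."""


class PlacentaDCEError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PlacentaDCEError, ValueError):
    """Input data violates a precondition (empty ROI, too few frames, ...)."""


class InvalidParameterError(PlacentaDCEError, ValueError):
    """A parameter value is out of its admissible range."""


class GridMismatchError(PlacentaDCEError, ValueError):
    """Two volumes that must share a voxel grid do not."""


class MetadataError(PlacentaDCEError, KeyError):
    """Acquisition metadata is missing or inconsistent."""


class DegenerateAIFError(PlacentaDCEError, ValueError):
    """The arterial input function carries no usable enhancement."""


class InvalidSpecError(PlacentaDCEError, ValueError):
    """A phantom specification is internally inconsistent."""
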