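"""Exception hierarchy for gliovol."""


class GliovolError(Exception):
    """Base class for all gliovol-specific errors."""


class VolumeFormatError(GliovolError):
    """Raised when a file cannot be interpreted as a 3-D scalar volume."""


class GridMismatchError(GliovolError):
    """Raised when a mask does not share the grid of its reference image."""


class DegenerateInputError(GliovolError):
    """Raised when an operation receives input it cannot meaningfully process
    (e.g. a constant-intensity region handed to two-class clustering)."""


class PipelineError(GliovolError):
    """Raised when an end-to-end run cannot produce a usable result."""
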