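"""Exception types shared across the package."""


class GrainstackError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(GrainstackError, ValueError):
    """Invalid acquisition geometry or mismatched stack geometries."""


class DegenerateInputError(GrainstackError, ValueError):
    """Input admits no meaningful answer (e.g. constant image, zero variance)."""
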