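"""Exception types shared across the package."""


class NeuromosaicError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(NeuromosaicError, ValueError):
    """A simulation/render/segmentation specification violates its invariants."""


class InsufficientDataError(NeuromosaicError, ValueError):
    """Too few points (or degenerate input) for the requested statistic."""


class AnnotationError(NeuromosaicError, ValueError):
    """A cortical annotation is geometrically inconsistent (e.g. crossing boundaries)."""
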