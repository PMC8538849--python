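"""Exception types shared across the package."""


class DensecgError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(DensecgError, ValueError):
    """A generator or topology spec violates its invariants."""


class TooShortError(DensecgError, ValueError):
    """An ECG record is too short for the requested analysis."""


class InsufficientBeatsError(DensecgError, ValueError):
    """Not enough detected beats for a beat-based computation."""


class ShapeError(DensecgError, ValueError):
    """Array dimensions are inconsistent with the model topology."""


class FormatError(DensecgError, ValueError):
    """A file does not conform to the expected on-disk format."""
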