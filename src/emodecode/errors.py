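"""Exception hierarchy.

Error messages carry the short diagnostic phrases used throughout the
package ("grid mismatch", "design mismatch", "invalid betas", ...) so
callers can match on either the class or the message.
"""


class EmodecodeError(Exception):
    """Base class for all package errors."""


class ConfigError(EmodecodeError):
    """Invalid configuration (bad enum value, inconsistent spec, bad YAML)."""


class GridMismatchError(EmodecodeError):
    """Spatial grids (betas, masks, maps) do not share dimensions or space."""


class DesignError(EmodecodeError):
    """Trial table violates the experimental design contract."""


class InvalidDataError(EmodecodeError):
    """Non-finite in-mask betas or otherwise unusable numeric data."""


class MaskError(EmodecodeError):
    """Empty mask, empty mask intersection, or empty trial selection."""


class CrossValidationError(EmodecodeError):
    """Fold construction impossible (single block, single-class training set)."""
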