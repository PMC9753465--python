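"""Exception hierarchy.

Every failure mode of the measurement pipeline maps onto one of these
classes so callers (and the CLI) can distinguish data problems (exit
code 1) from configuration problems (exit code 2).
"""


class AmisQuantError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(AmisQuantError):
    """A geometric precondition failed (path out of bounds, impossible
    cell placement, disc outside a mask, interface too short...)."""


class DetectionError(AmisQuantError):
    """A signal feature (e.g. an actin end peak) could not be detected."""


class MaskError(AmisQuantError):
    """A region mask is empty, overlapping, or otherwise invalid."""


class UndefinedRatioError(AmisQuantError):
    """A ratio denominator is zero; the ratio is undefined, never NaN."""


class DegenerateTraceError(AmisQuantError):
    """A FRAP trace carries no usable bleach signal (F_i == F_0 or F_i <= 0)."""


class FitError(AmisQuantError):
    """Non-linear fitting failed to converge after bounded restarts."""


class FormatError(AmisQuantError):
    """An input file could not be interpreted (missing calibration,
    ambiguous axes, malformed annotation)."""


class ConfigError(AmisQuantError):
    """A run configuration is invalid (unknown key, missing input)."""
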