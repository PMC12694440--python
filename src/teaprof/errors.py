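"""Exception hierarchy for the canopy-analysis pipeline.

Each failure mode the pipeline can hit maps to one exception class so the
CLI can translate them into distinct exit codes.
"""


class TeaprofError(Exception):
    """Base class for all package errors."""


class ParameterError(TeaprofError, ValueError):
    """An input value violates a documented precondition; names the field."""


class DegenerateHistogramError(TeaprofError):
    """Otsu thresholding was asked to split fewer than two gray levels."""


class LightingOutOfRangeError(TeaprofError):
    """Frame AG falls outside both configured lighting bands."""


class InsufficientEvidenceError(TeaprofError):
    """Too few valid shoot pixels in a region to average a depth."""


class MechanismLimitError(TeaprofError):
    """Requested cutter rotation is outside the linkage's reachable range."""


class ConfigError(TeaprofError):
    """A configuration file or table failed validation at load time."""
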