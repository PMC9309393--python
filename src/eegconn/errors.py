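"""Exception hierarchy shared across the package."""


class EegConnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EegConnError, ValueError):
    """Malformed input file (ragged rows, duplicate labels, bad numbers)."""


class ConfigError(EegConnError, ValueError):
    """Inconsistent or missing configuration (sampling rate, WPD depth, ...)."""


class DomainError(EegConnError, ValueError):
    """Input outside the mathematical domain of an operation."""


class EstimationError(EegConnError, ValueError):
    """Estimator would be degenerate on this input (e.g. < 2 Welch segments)."""


class AlignmentError(EegConnError, ValueError):
    """Two matrices refer to different channel sets or orderings."""


class MontageLookupError(EegConnError, KeyError):
    """A channel label cannot be resolved in the active montage."""
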