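"""Exception hierarchy for the interadapt pipeline."""


class InterAdaptError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(InterAdaptError):
    """Invalid configuration or parameter values."""


class NoOnsetError(InterAdaptError):
    """Movement onset could not be determined (flat or featureless speed trace)."""


class NoCrossingError(InterAdaptError):
    """The hand path never crosses the target's trajectory line."""


class TargetRangeError(InterAdaptError):
    """Crossing position lies outside the range the target traverses."""


class TooFewTrialsError(InterAdaptError):
    """Not enough valid trials for the requested computation."""


class DegenerateDataError(InterAdaptError):
    """Input has no variance (or is otherwise degenerate) where variance is required."""
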