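"""Exception hierarchy.

Every error raised by the package derives from :class:`EVQuantError` so
pipelines can catch one base class and report the failing stage.
"""


class EVQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EVQuantError):
    """Invalid or inconsistent user configuration (channel maps, specs)."""


class InputError(EVQuantError):
    """Malformed input data (dimension mismatch, empty stack, ...)."""


class AnalysisError(EVQuantError):
    """A computation cannot proceed on the given data (empty mask, ...)."""


class DegenerateThresholdError(AnalysisError):
    """Automatic thresholding on a constant (single-level) image."""


class PlacementError(AnalysisError):
    """Monte Carlo randomization could not place a particle inside the ROI."""


class UndefinedStatisticError(AnalysisError):
    """A statistic is undefined for the sample (n too small, zero variance)."""


class GenerationError(EVQuantError):
    """The synthetic-data generator could not realize the requested spec."""
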