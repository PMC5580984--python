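"""Exception hierarchy used across the package."""


class FlowfectError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FlowfectError):
    """A role map, channel assignment or run configuration is invalid."""


class FormatError(FlowfectError):
    """An input file could not be parsed as the declared format."""


class InsufficientDataError(FlowfectError):
    """Too few events to fit a gate, a threshold or a statistic."""


class CalibrationQualityError(FlowfectError):
    """Bead peaks merged or the standard curve fit is below the quality bar."""


class DataError(FlowfectError):
    """Inputs are structurally valid but numerically unusable (e.g. constant
    vector for a rank correlation, non-monotone bead/known pairing)."""
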