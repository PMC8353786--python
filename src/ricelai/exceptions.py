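"""Exception hierarchy for the rice LAI pipeline."""


class RiceLAIError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RiceLAIError):
    """A configuration value is inconsistent or refers to something absent."""


class SingularFitError(RiceLAIError):
    """A least-squares fit is degenerate (constant predictor / too few points)."""


class UndefinedValueError(RiceLAIError):
    """A quantity is mathematically undefined for the given inputs."""


class EmptyROIError(RiceLAIError):
    """All pixels of a region of interest were masked out."""


class BoundsError(RiceLAIError):
    """A region of interest falls outside the raster grid."""


class LayoutError(ConfigurationError):
    """A synthetic scene layout cannot accommodate the requested content."""
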