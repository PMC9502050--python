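"""Exception hierarchy shared across the pipeline stages."""


class EpomrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpomrError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(EpomrError):
    """A required column or field is missing or malformed."""


class DegenerateInputError(EpomrError):
    """Input has no usable variation (e.g. all phenotype values identical)."""


class NumericalDesignError(EpomrError):
    """Rank-deficient or otherwise unusable regression design."""


class CollinearityError(EpomrError):
    """A selected-variant LD submatrix is singular or near-singular."""


class WeakInstrumentError(EpomrError):
    """The instrument has a zero (or unusable) exposure effect."""


class OrchestrationError(EpomrError):
    """A pipeline stage is missing an upstream dependency."""
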