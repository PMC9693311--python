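"""Exception hierarchy shared across the package."""


class EarMorphError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EarMorphError, ValueError):
    """Malformed or out-of-contract data passed to an operation."""


class InvalidConfigError(EarMorphError, ValueError):
    """A configuration value outside its documented range."""


class DegenerateRegistrationError(EarMorphError):
    """Too few or geometrically degenerate correspondences for a rigid fit."""


class CorrespondenceError(EarMorphError):
    """Shapes claimed to be in dense correspondence do not share a topology."""


class FittingError(EarMorphError):
    """Model fitting failed irrecoverably; carries the iteration index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class PipelineError(EarMorphError):
    """A multi-stage pipeline could not produce a usable result."""


class IncompatibilityError(EarMorphError):
    """Shape parameters and gallery/model built from different models."""


class UndefinedDistanceError(EarMorphError):
    """A dissimilarity is undefined for the given vectors (e.g. cosine of 0)."""


class NumericalError(EarMorphError):
    """A numerical operation failed (e.g. singular covariance); names the op."""


class ParseError(EarMorphError):
    """A scan or container file could not be parsed."""


class IntegrityError(EarMorphError):
    """A serialized container failed its internal consistency checks."""
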