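"""Exception hierarchy for the SOC-GWR pipeline.

Every failure mode named by the pipeline contracts maps to one of these, so
callers can distinguish bad arguments from degenerate data or geometry
mismatches without string matching.
"""


class SocGwrError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SocGwrError, ValueError):
    """An argument violates a precondition (dimension, range, missing name)."""


class DomainError(SocGwrError, ValueError):
    """A value lies outside the mathematical domain of a transform."""


class EmptyWindowError(SocGwrError):
    """No soil layer intersects the requested depth window."""


class DegenerateTruthError(SocGwrError):
    """Synthetic truth repeatedly produced responses outside the Box-Cox
    inverse domain; the coefficient surfaces or noise level are untenable."""


class MissingLayerError(SocGwrError, KeyError):
    """A named predictor layer is absent from the stack."""


class CoRegistrationError(SocGwrError):
    """Two gridded products do not share (or overlap in) geometry."""


class SingularFitError(SocGwrError):
    """A local weighted least-squares system is singular and no ridge
    jitter was allowed to resolve it."""


class OversmoothingError(SocGwrError):
    """The effective parameter count leaves no residual degrees of freedom
    (n - 2 - trace(S) <= 0), so AICc is undefined at this bandwidth."""


class SearchFailureError(SocGwrError):
    """No candidate bandwidth produced a finite AICc."""


class UndefinedR2Error(SocGwrError):
    """R-squared is undefined because the observed values have no variance."""


class MissingInputError(SocGwrError, FileNotFoundError):
    """A pipeline stage requires an artifact that an earlier stage has not
    written yet; carries the artifact name."""
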