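"""Exception and warning types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An invalid simulation or analysis configuration."""


class ScoringFileError(ValueError):
    """A malformed variant scoring file; the message names the offending line."""


class SeparationError(RuntimeError):
    """Logistic fit failed to converge or shows (quasi-)complete separation.

    Carries the diagnostics of the failed fit in ``diagnostics``.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateReferenceError(ValueError):
    """The reference distribution cannot support the requested transform."""


class StrandAmbiguityWarning(UserWarning):
    """A/T or C/G variant retained; orientation cannot be checked by alleles."""


class AmbiguousFindingWarning(UserWarning):
    """A colonoscopy finding whose classification the study rules leave open."""


class EmptyCellWarning(UserWarning):
    """A cell of a joint cross-classification contains no participants."""
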