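"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model or scenario parameter lies outside its admissible range."""


class InvalidInputError(ValueError):
    """Input vectors are malformed (wrong values, mismatched lengths, ...)."""


class DegenerateOutcomeError(InvalidInputError):
    """The outcome vector is constant (all cases or all controls)."""


class DegeneratePredictorError(InvalidInputError):
    """The genotype vector is constant, so the slope is unidentifiable."""


class UndefinedRateError(InvalidInputError):
    """Misclassification rate is undefined (zero true prevalence)."""


class InconsistentPrevalenceError(InvalidInputError):
    """Observed prevalence exceeds true prevalence, violating the
    case-only (underdiagnosis) misclassification assumption."""


class UnidentifiableError(InvalidInputError):
    """The mediator carries no signal, so the reverse-mediation
    estimand is unidentifiable."""
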