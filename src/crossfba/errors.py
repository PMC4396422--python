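"""Exception hierarchy for crossfba."""


class CrossFBAError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CrossFBAError):
    """A model or config file could not be parsed under the named format."""


class ModelValidationError(CrossFBAError):
    """A stoichiometric model violates its structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "model failed validation:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class NumericalError(CrossFBAError):
    """The LP solver failed for a reason other than infeasibility."""


class OverdrawError(CrossFBAError):
    """A shared metabolite pool remained overdrawn after bound rescaling."""


class DegenerateVarianceError(CrossFBAError):
    """All within-group absolute deviations are zero; Levene W is undefined."""


class ExtinctCommunityError(CrossFBAError):
    """Both species reached zero biomass; composition is undefined."""


class UndefinedReferenceError(CrossFBAError):
    """The unperturbed reference biomasses are all zero; metric undefined."""


class InsufficientDataError(CrossFBAError):
    """Too few usable mutants to build the requested summary."""
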