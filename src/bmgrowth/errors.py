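"""Domain-specific exceptions.

All estimation and simulation failure modes raise one of these so that
callers (the CLI, the cohort pipeline) can distinguish "bad input" from
"no solution exists for this input".
"""


class BMGrowthError(Exception):
    """Base class for all package errors."""


class ValidationError(BMGrowthError, ValueError):
    """Input violates a documented precondition or invariant."""


class DomainError(BMGrowthError, ValueError):
    """Evaluation requested outside a model's valid domain (e.g. past blow-up)."""


class NoRootError(BMGrowthError):
    """The implicit exponent equation has no sign change in the search bracket."""


class AmbiguousRootError(BMGrowthError):
    """More than one root found in the bracket; all candidates are reported."""

    def __init__(self, roots):
        self.roots = list(roots)
        super().__init__(f"multiple roots found: {self.roots}")


class ExclusionError(BMGrowthError):
    """Series excluded by a filtering rule (e.g. decreasing volumes)."""


class NoFitError(BMGrowthError):
    """No feasible candidate on the volume grid for the requested exponent."""


class ScreenUndefinedError(BMGrowthError):
    """All perturbation replicates failed; the screen mean is undefined."""


class ConfigurationError(BMGrowthError, ValueError):
    """Simulator configuration yields invalid per-step probabilities."""


class TreatmentError(BMGrowthError):
    """Requested post-treatment composition is infeasible for this state."""


class SamplingError(BMGrowthError):
    """Could not sample a monotone three-point record from a trajectory."""
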