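"""Exception hierarchy for the ensemble allosteric model package."""


class GrEamError(Exception):
    """Base class for all package-specific errors."""


class ModelError(GrEamError):
    """A ProteinModel (or a file describing one) is malformed."""


class ModelParseError(ModelError):
    """A model file failed validation; message names the offending field."""


class ObservableUndefinedError(GrEamError):
    """The requested observable needs a domain role the model does not have."""


class DegenerateConfigurationError(GrEamError):
    """A coupling-sign configuration contains a zero (sign-less) coupling."""


class BudgetExceededError(GrEamError):
    """The requested grid is larger than the configured evaluation budget."""

    def __init__(self, required: int, budget: int):
        self.required = required
        self.budget = budget
        super().__init__(
            f"grid search requires {required} evaluations, exceeding the "
            f"budget of {budget}; raise the budget or coarsen the grid"
        )


class InfeasibleSpaceError(GrEamError):
    """Sign constraints leave no feasible grid point for some parameter."""


class InconsistentFamilyError(GrEamError):
    """A dataset row requires an observable the construct's model cannot define."""


class FitConvergenceError(GrEamError):
    """A nonlinear least-squares fit failed to converge or is unidentifiable."""
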