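"""Exception types shared across the package."""


class VlsuppError(Exception):
    """Base class for package errors."""


class ConfigurationError(VlsuppError):
    """A configuration value is missing, unknown or inconsistent."""


class DataValidationError(VlsuppError):
    """Input data violate a precondition (bad values, wrong dtype, ...)."""


class ContractViolationError(VlsuppError):
    """An operation was called outside its contract (programming error)."""


class RankDeficiencyError(VlsuppError):
    """The design matrix is not full column rank."""

    def __init__(self, aliased_columns):
        self.aliased_columns = list(aliased_columns)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(self.aliased_columns)
        )


class ConvergenceError(VlsuppError):
    """An MCMC fit failed its convergence checks."""
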