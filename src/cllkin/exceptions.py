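"""Exception hierarchy shared across the package."""


class CllkinError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CllkinError):
    """Invalid parameter values, model specification or configuration."""


class IntegrationError(CllkinError):
    """The numerical ODE solver failed for a given parameter set."""


class SchemaError(CllkinError):
    """An input table violates the cohort file schema."""


class MissingCovariateError(CllkinError):
    """A required clinical covariate is absent (no silent default)."""


class DegenerateVarianceError(CllkinError):
    """A statistic is undefined because the sample variance is zero."""


class NonConvergenceError(CllkinError):
    """An optimiser or stochastic estimator failed to converge."""


class PipelineError(CllkinError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
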