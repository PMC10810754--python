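"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation errors -> 2, coverage
errors -> 3, infeasibility -> 4.
"""


class NutriscenError(Exception):
    """Base class for all package errors."""


class ValidationError(NutriscenError):
    """Invalid scenario, configuration or input data."""


class ConfigError(ValidationError):
    """Invalid generator or scoring configuration."""


class DataError(NutriscenError):
    """Inconsistent or degenerate input data (e.g. zero feed with output)."""


class CoverageError(NutriscenError):
    """A table does not cover a commodity/category it is required to cover."""


class AccountingError(NutriscenError):
    """A food-balance identity cannot be satisfied (e.g. negative food)."""


class AllocationInfeasibleError(NutriscenError):
    """The land-allocation problem has no feasible solution."""

    def __init__(self, message: str, constraints: list[str] | None = None):
        super().__init__(message)
        self.constraints = constraints or []


class ScoringError(NutriscenError):
    """Indicators required for scoring a scenario are missing."""
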