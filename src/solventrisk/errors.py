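"""Exception hierarchy shared across the package."""


class SolventRiskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SolventRiskError, ValueError):
    """A scenario, distribution or reference-value configuration is unusable."""


class DataError(SolventRiskError, ValueError):
    """Input samples violate a distribution's support or are degenerate."""


class MissingReferenceError(SolventRiskError, LookupError):
    """No reference concentration or dose is available for a chemical/toxicity pair."""


class UndefinedCoefficientError(SolventRiskError, ValueError):
    """A rank correlation is undefined (constant input)."""


class ScenarioValidationError(ConfigurationError):
    """A scenario file failed validation; carries the itemized problem list."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "scenario validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )
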