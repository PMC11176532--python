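"""Exception hierarchy for mrkit."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A file, column map, or config value is unusable."""


class ValidationError(MRKitError):
    """An input row violates a summary-statistics invariant.

    Carries the offending row number (1-based, excluding header) and field
    name when known.
    """

    def __init__(self, message, row=None, field=None):
        super().__init__(message)
        self.row = row
        self.field = field


class EstimationError(MRKitError):
    """An estimator cannot be computed on the given data."""


class InsufficientInstrumentsError(EstimationError):
    """Fewer instruments than the estimator's minimum."""


class ScenarioError(MRKitError):
    """A synthetic-data scenario is infeasible as parameterized."""
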