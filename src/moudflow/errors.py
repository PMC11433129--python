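"""Exception hierarchy.

Errors are grouped so the CLI can map them to distinct exit codes:
configuration (bad user input), schema/validation (bad data), and
contract (programming errors at module boundaries).
"""


class MoudflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MoudflowError):
    """Invalid generator or run configuration (probability vectors, fractions)."""


class SchemaError(MoudflowError):
    """A required column or codebook variable is missing."""


class ValidationError(MoudflowError):
    """Data values do not resolve against the codebook."""


class BalancingError(MoudflowError):
    """Class balancing is impossible (an outcome class is absent)."""


class SplitError(MoudflowError):
    """Too few rows to form the requested partitions."""


class TuningError(MoudflowError):
    """Hyperparameter search cannot run (degenerate labels, empty budget)."""


class ContractError(MoudflowError):
    """An internal interface contract was violated (shape/feature mismatch)."""
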