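"""Exception hierarchy for strataprs."""


class StrataprsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StrataprsError, ValueError):
    """An input value violates a documented invariant."""


class SumstatsFormatError(StrataprsError, ValueError):
    """A summary-statistics file is malformed (e.g. missing columns)."""


class DegenerateIntervalError(ValidationError):
    """A confidence interval has zero width, so no SE can be recovered."""


class HarmonizationError(StrataprsError, ValueError):
    """Two records for the same variant cannot be aligned to one effect allele."""


class SimulationBudgetError(StrataprsError, RuntimeError):
    """The case/control quota could not be filled within the draw budget."""
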