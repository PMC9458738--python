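"""Exception hierarchy for trial-data validation and analysis."""


class SelgainError(Exception):
    """Base class for all package errors."""


class SchemaError(SelgainError):
    """Input table is missing required columns or has malformed values."""


class BalanceError(SelgainError):
    """A randomized-complete-block table is not balanced."""


class DesignError(SelgainError):
    """Operation applied to a table with the wrong experimental design."""


class DegreesOfFreedomError(SelgainError):
    """Too few families or replicates for the requested decomposition."""


class ComponentError(SelgainError):
    """Inconsistent or degenerate variance-component inputs."""


class UndefinedStatisticError(SelgainError):
    """A statistic is undefined for the given inputs (e.g. zero variance)."""


class IndexConstructionError(SelgainError):
    """Selection-index weights cannot be computed (e.g. ill-conditioned P)."""
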