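"""Package-wide exception types."""


class VaporDoseError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(VaporDoseError, ValueError):
    """A function argument violates its precondition."""


class ConfigurationError(VaporDoseError, ValueError):
    """A scenario configuration is inconsistent or incomplete."""


class UndefinedBudgetError(VaporDoseError, ZeroDivisionError):
    """An exposure budget was requested for a run with zero inhaled mass."""


class NonIdentifiableError(VaporDoseError, RuntimeError):
    """A parameter-recovery problem has no information about the parameter."""
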