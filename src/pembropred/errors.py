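"""Exception hierarchy shared across the package."""


class PembropredError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PembropredError, ValueError):
    """A quantity lies outside its mathematically valid domain."""


class InputError(PembropredError, ValueError):
    """A patient record or cohort violates the input contract."""


class ConfigError(PembropredError, ValueError):
    """A run or cohort configuration is inconsistent."""


class ParseError(PembropredError, ValueError):
    """A CSV/YAML input file could not be parsed."""


class IntegrationError(PembropredError, RuntimeError):
    """The ODE solver failed before reaching the end of the horizon."""


class UndefinedStatisticError(PembropredError, ValueError):
    """A requested statistic is undefined for the given data
    (zero variance, single-class labels, degenerate marginals...)."""
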