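"""Exception hierarchy shared across the package.

Each exception maps to one class of user-facing failure so the CLI can
translate them into stable exit codes (data errors vs numerical failures).
"""


class SmallCrtError(Exception):
    """Base class for all package errors."""


class DataFormatError(SmallCrtError):
    """A delimited input file does not match the expected layout."""


class DataConsistencyError(SmallCrtError):
    """Input rows are individually valid but mutually inconsistent
    (e.g. the arm label varies within a cluster, duplicated cluster ids)."""


class ValidationError(SmallCrtError):
    """A record violates an invariant (e.g. events > size)."""


class DesignError(SmallCrtError):
    """The trial layout cannot be analysed (e.g. fewer than two clusters
    in an arm, or a single-arm dataset)."""


class ConfigurationError(SmallCrtError):
    """An invalid scenario, method label, or run configuration."""


class NumericalError(SmallCrtError):
    """A numerical procedure failed in a way that is not representable as
    a non-converged result (e.g. infeasible effect-size solve)."""
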