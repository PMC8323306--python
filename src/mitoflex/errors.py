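"""Exception hierarchy shared across the package.

Exit-code convention used by the CLI: validation problems (bad inputs,
incomplete configuration) map to exit code 1, runtime failures (solver
non-convergence, stage crashes) to exit code 2.
"""


class MitoflexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MitoflexError):
    """Missing or inconsistent configuration (e.g. an enzyme without parameters)."""


class DomainError(MitoflexError, ValueError):
    """Input outside the mathematical domain of an operation (negative
    concentration, zero standard intensity, ...)."""


class ConvergenceError(MitoflexError, RuntimeError):
    """A solver or fitter failed to converge within its budget."""


class UndefinedResultError(MitoflexError):
    """The requested quantity is undefined for these inputs (e.g. an FCC at
    zero flux, or MISI for a monotonically rising glucose curve)."""
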