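"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: configuration errors → 2, data/parse
errors → 3, convergence failures → 4.
"""


class SVLocusError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SVLocusError):
    """Invalid configuration, parameters, or preset definitions."""


class MappingError(SVLocusError):
    """A coordinate cannot be lifted between allele and reference."""


class ParseError(SVLocusError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConvergenceError(SVLocusError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, n_iter: int | None = None,
                 residual: float | None = None):
        self.n_iter = n_iter
        self.residual = residual
        super().__init__(message)
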