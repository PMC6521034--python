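"""Exception hierarchy shared across the package."""


class NutricompileError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NutricompileError):
    """A required column is missing or a file does not match its schema."""


class RowParseError(NutricompileError):
    """One or more rows of an input table could not be parsed.

    Carries the offending 0-based row indices (relative to the first data
    row) in :attr:`rows`.
    """

    def __init__(self, message: str, rows=()):
        super().__init__(message)
        self.rows = list(rows)


class ConfigError(NutricompileError):
    """Invalid configuration (overlapping reference bands, bad mapping, ...)."""


class ValidationError(NutricompileError):
    """A parsed object violates a domain invariant."""


class CompilationError(NutricompileError):
    """Database compilation failed (unresolved ingredient, policy violation)."""

    def __init__(self, message: str, ids=()):
        super().__init__(message)
        self.ids = list(ids)


class CycleError(CompilationError):
    """Nested recipes form a dependency cycle; :attr:`cycle` names it."""

    def __init__(self, message: str, cycle=()):
        super().__init__(message, ids=cycle)
        self.cycle = list(cycle)


class AdjustmentError(NutricompileError):
    """A compositional adjustment is not applicable (e.g. zero donor protein)."""


class EstimationError(NutricompileError):
    """A statistical quantity is unidentifiable from the given data."""
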