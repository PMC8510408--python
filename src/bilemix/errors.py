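"""Exception hierarchy shared across the analysis stages."""


class BilemixError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BilemixError, ValueError):
    """Input violates a physical or mathematical precondition."""


class NoPhysicalRootError(BilemixError):
    """The regular-solution composition equation has no root in (0, 1).

    Signals an inconsistent (alpha, C12, C1, C2) quadruple, e.g. a mixed
    CMC far outside the range bracketed by the pure-component CMCs.
    """


class IllConditionedError(BilemixError):
    """A solution exists but sits too close to a boundary to be trusted."""


class NoBreakpointError(BilemixError):
    """A titration curve shows no detectable micellization breakpoint."""


class InsufficientDataError(BilemixError):
    """Too few usable data points for the requested estimate."""


class FittingError(BilemixError):
    """Nonlinear least squares failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(BilemixError, ValueError):
    """Tabular input does not match its declared schema."""
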