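"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`AllokitError`,
so callers (and the CLI) can distinguish bad input (exit code 2) from a fit
that failed to converge (exit code 3).
"""


class AllokitError(Exception):
    """Base class for all allokit errors."""


class InvalidParameterError(AllokitError, ValueError):
    """A model parameter is non-finite or outside its physical domain."""


class ParseError(AllokitError, ValueError):
    """Malformed tabular input (missing column, bad units, non-monotone grid)."""


class MissingControlError(AllokitError, ValueError):
    """Relative dissociation rates requested but no modulator-free trace given."""


class FitFailureError(AllokitError, RuntimeError):
    """Optimisation did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnidentifiableError(AllokitError, ValueError):
    """The data cannot constrain the requested parameters (e.g. collinear
    reference spectra, or a saturation curve with no specific component)."""


class InfeasibleParameterError(AllokitError, ValueError):
    """No physical solution exists for the given parameters (e.g. the implicit
    bound-ligand equation has no root on its bracket)."""


class PairingError(AllokitError, ValueError):
    """Paired before/after samples have mismatched lengths or identities."""


class UndefinedScalingError(AllokitError, ZeroDivisionError):
    """Replicate normalisation hit f(x, a, b) = 0."""
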