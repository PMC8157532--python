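"""Exception types shared across the package."""


class DyndesignError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DyndesignError, ValueError):
    """An input object violates its documented invariants."""


class TimescaleSeparationError(DyndesignError, ValueError):
    """Microstate expansion would not be well separated from macrostate kinetics."""


class ConvergenceError(DyndesignError, RuntimeError):
    """An iterative estimator failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConnectivityError(DyndesignError, ValueError):
    """A state set required to be connected / reachable is not."""


class DegenerateSpectrumError(DyndesignError, ValueError):
    """Eigenvalue degeneracy at the requested spectral cut."""


class MissingEmissionError(DyndesignError, KeyError):
    """A trajectory visits a state with no emission parameters."""


class SchemaError(DyndesignError, ValueError):
    """A file does not conform to the declared on-disk schema."""
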