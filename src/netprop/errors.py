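"""Exception hierarchy shared across the pipeline."""


class NetpropError(Exception):
    """Base class for all package errors."""


class ParseError(NetpropError):
    """A line of an input file could not be parsed."""


class EmptyNetworkError(NetpropError):
    """Filtering left no edges in the interactome."""


class ValidationError(NetpropError):
    """An argument violates a documented precondition."""


class LookupError_(NetpropError):
    """A gene identifier is not present in the network."""


class ConvergenceError(NetpropError):
    """Iterative diffusion failed to reach the tolerance.

    Carries the last residual so callers can inspect how far the
    iteration was from the fixed point.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class GenerationError(NetpropError):
    """The synthetic generator could not satisfy its constraints."""
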