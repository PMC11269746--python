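"""Exception types shared across the package."""


class ConvlossError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(ConvlossError, ValueError):
    """An argument violates a documented precondition."""


class DataError(ConvlossError, ValueError):
    """Input data are structurally inconsistent (missing node, all-gap row, ...)."""


class TreeError(ConvlossError, ValueError):
    """A tree is malformed or a topology precondition fails."""


class TopologyError(TreeError):
    """Outgroup/ingroup arrangement contradicts the requested rooting."""


class ConvergenceFailure(ConvlossError, RuntimeError):
    """An optimizer failed to converge after retries."""


class SamplerFailure(ConvlossError, RuntimeError):
    """An MCMC chain accepted no proposals over its full run."""


class NoSingleLossError(ConvlossError, ValueError):
    """No reconstruction replicate shows exactly one loss along the path."""


class ParseError(ConvlossError, ValueError):
    """A structured text input could not be parsed."""


class GenerationError(ConvlossError, RuntimeError):
    """A synthetic fixture could not be generated under its geometric constraints."""
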