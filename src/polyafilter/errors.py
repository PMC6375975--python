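"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`PolyaError`,
so callers (and the CLI) can distinguish validation problems from genuine bugs.
"""


class PolyaError(Exception):
    """Base class for all errors raised by polyafilter."""


class FormatError(PolyaError, ValueError):
    """Malformed edge-list input (bad line, duplicate link, self-loop, ...)."""


class DomainError(PolyaError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class ModeError(PolyaError, ValueError):
    """Requested p-value mode incompatible with the data (e.g. exact on real weights)."""


class DegenerateLikelihoodError(PolyaError):
    """The network carries no information about the reinforcement parameter
    (no viewpoint with degree >= 2)."""


class UnreachableTargetError(PolyaError):
    """sweep_a could not reach the requested sparsity within the searched range."""
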