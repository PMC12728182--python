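"""Package-wide exception types."""


class FoldbindError(Exception):
    """Base class for errors raised by this package."""


class InvalidInputError(FoldbindError, ValueError):
    """An argument violates a documented precondition."""


class ConsistencyError(FoldbindError, RuntimeError):
    """An internal invariant that should hold by construction was violated."""


class ConvergenceError(FoldbindError, RuntimeError):
    """An optimisation failed to converge and no usable result exists."""
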