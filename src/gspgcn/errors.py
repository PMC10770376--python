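"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class EmptyResultError(RuntimeError):
    """An operation produced no usable output (e.g. every trial rejected)."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class InvalidStateError(RuntimeError):
    """An object is not in a state that permits the requested operation."""
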