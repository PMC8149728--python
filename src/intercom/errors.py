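"""Exception hierarchy shared by all pipeline stages."""


class InterComError(Exception):
    """Base class for all package errors."""


class FormatError(InterComError):
    """An input file violates its declared format (missing columns, bad values)."""


class ValidationError(InterComError):
    """Inputs are well-formed but semantically unusable (empty scaffold, no TFs...)."""


class ConvergenceError(InterComError):
    """Power iteration failed to reach the requested tolerance.

    Carries the last iterate so callers can inspect or restart with damping.
    """

    def __init__(self, message, last_iterate=None, iterations=None, residual=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.iterations = iterations
        self.residual = residual
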