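"""Exception hierarchy."""


class GlufaError(Exception):
    """Base class for package errors."""


class InvalidInputError(GlufaError, ValueError):
    """Malformed data or out-of-contract arguments."""


class InvalidParameterError(GlufaError, ValueError):
    """Parameter set violates a model invariant."""


class IntegrationError(GlufaError, RuntimeError):
    """ODE solver failed to produce a trajectory."""


class NonConvergenceError(GlufaError, RuntimeError):
    """No optimizer start reached a converged local optimum."""


class NoSteadyStateError(GlufaError, ValueError):
    """Model has no finite fixed point for the given parameters."""
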