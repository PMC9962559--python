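"""Exception hierarchy shared across the package."""


class OxirelaxError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OxirelaxError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(InvalidInputError):
    """Input is formally valid but carries no usable signal (e.g. a constant curve)."""


class ConfigurationError(OxirelaxError, ValueError):
    """A configuration object is internally inconsistent."""


class ConvergenceError(OxirelaxError, RuntimeError):
    """An iterative solver failed to reach its tolerance.

    Carries the iteration count at which the solver gave up.
    """

    def __init__(self, message: str, iterations: int):
        super().__init__(message)
        self.iterations = iterations


class LabelConflictError(OxirelaxError, ValueError):
    """Diffusion and peroxide criteria imply different classes under the strict policy."""

    def __init__(self, message: str, d_class=None, pv_class=None):
        super().__init__(message)
        self.d_class = d_class
        self.pv_class = pv_class


class CurveParseError(OxirelaxError, ValueError):
    """A curve file could not be parsed; names the offending line when known."""
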