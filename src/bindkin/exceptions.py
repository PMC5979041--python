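"""Named exceptions shared across the pipeline."""


class BindkinError(Exception):
    """Base class for all package errors."""


class NotIrreducibleError(BindkinError):
    """Kinetic network / count graph is not a single communicating class."""


class SingularSystemError(BindkinError):
    """A linear system that should be solvable is singular (reducible chain)."""


class NonFiniteDynamicsError(BindkinError):
    """Non-finite energy, gradient or position encountered during integration."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class ConvergenceError(BindkinError):
    """Iterative estimator failed to converge within its iteration cap."""


class CensoredRunError(BindkinError):
    """Enhanced-sampling run ended without the escape event occurring."""


class WindowOverlapError(BindkinError):
    """Umbrella windows do not overlap; WHAM cannot stitch them."""


class ParseError(BindkinError):
    """Malformed structure/trajectory input."""
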