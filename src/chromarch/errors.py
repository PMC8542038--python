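"""Exception hierarchy shared by all stages.

Every error raised on a contract violation derives from :class:`ChromarchError`
so the CLI can map failures onto stable exit codes (2 validation, 3
convergence, 4 I/O).
"""


class ChromarchError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(ChromarchError, ValueError):
    """A parameter is outside its documented domain."""

    exit_code = 2


class ValidationError(ChromarchError, ValueError):
    """A configuration or input fails validation before any compute."""

    exit_code = 2


class FormatError(ChromarchError, ValueError):
    """An input file does not parse or references unknown bins/chromosomes."""

    exit_code = 4


class StateError(ChromarchError, ValueError):
    """An operation received a matrix in the wrong normalization state."""

    exit_code = 2


class DegeneracyError(ChromarchError, ValueError):
    """Too little usable data for the operation (e.g. all bins masked)."""

    exit_code = 2


class DomainError(ChromarchError, ValueError):
    """A bin pair is outside the operation's spatial domain."""

    exit_code = 2


class AlignmentError(ChromarchError, ValueError):
    """Two inputs that must share a bin grid do not."""

    exit_code = 2


class ConvergenceError(ChromarchError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    exit_code = 3

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class AmbiguousOrientationError(ChromarchError, ValueError):
    """Histone-mark evidence is too weak to orient the compartment eigenvector.

    Raised instead of silently guessing a sign; callers may set the sign
    manually or lower the ambiguity threshold.
    """

    exit_code = 2


class IntegrationError(ChromarchError, RuntimeError):
    """The 3D optimizer produced non-finite energy (step size too large)."""

    exit_code = 3
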