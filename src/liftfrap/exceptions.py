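"""Exception hierarchy for liftfrap.

All package errors derive from :class:`LiftFrapError` so callers can catch
one base class.  Validation failures (bad inputs, malformed configs) are
distinguished from numerical/analysis failures because the command-line
interface maps them to different exit codes.
"""


class LiftFrapError(Exception):
    """Base class for all liftfrap errors."""


class ValidationError(LiftFrapError, ValueError):
    """Input or configuration violates a documented precondition."""


class UndefinedInputError(ValidationError):
    """Input is syntactically valid but the quantity is mathematically
    undefined for it (e.g. fractional anisotropy of an all-zero tensor)."""


class AnalysisError(LiftFrapError, RuntimeError):
    """A numerical stage of an analysis pipeline failed (non-convergence,
    rank deficiency, signal below the noise floor, ...)."""


class StabilityError(ValidationError):
    """Requested explicit time step violates the solver stability bound."""
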