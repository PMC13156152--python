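"""Exception hierarchy shared across the package."""

__all__ = ["EquilocError", "InputError", "FormatError", "InfeasibleError",
           "SolverError"]


class EquilocError(Exception):
    """Base class for package errors."""


class InputError(EquilocError, ValueError):
    """Invalid in-memory input (shape, range, emptiness)."""


class FormatError(EquilocError, ValueError):
    """Malformed on-disk input; the message names the offending cell."""


class InfeasibleError(EquilocError, RuntimeError):
    """The optimization model admits no feasible allocation.

    ``reason`` names the first violated necessary condition when one can be
    identified before solving, otherwise reports the solver verdict.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class SolverError(EquilocError, RuntimeError):
    """The MILP backend failed for a reason other than infeasibility."""
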