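"""Typed errors raised across the package.

Every rejection names the violated invariant in its message so that CLI
users see exactly which design constraint failed.
"""


class NCCPVError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(NCCPVError):
    """The sampling design itself is impossible (e.g. empty control pool,
    more controls requested than the cohort contains, zero sampled
    controls)."""

    exit_code = 4


class ValidationError(NCCPVError):
    """Counts or configuration values violate a type invariant."""

    exit_code = 2


class DegenerateTableError(NCCPVError):
    """A denominator needed for the requested estimate is empty (e.g. no
    test-positive subjects when estimating the PPV). A Haldane-Anscombe
    continuity correction can be enabled to proceed."""

    exit_code = 2


class BoundaryError(NCCPVError):
    """Estimated sensitivity or specificity sits on the boundary {0, 1},
    where the delta-method variances are undefined or degenerate."""

    exit_code = 2


class SeparationError(NCCPVError):
    """A zero cell makes the saturated logistic fit non-identifiable
    (maximum likelihood on the boundary)."""

    exit_code = 3


class ConvergenceError(NCCPVError):
    """Iterative fitting exceeded its iteration budget; carries the
    iteration trace for diagnosis."""

    exit_code = 3

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []
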