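"""Exception hierarchy.

Recoverable physical conditions (an empty bladder produces no posterior
echo) are distinct classes so callers can branch on them instead of
parsing messages.
"""


class EchovolError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EchovolError, ValueError):
    """A precondition on an argument was violated."""


class NoEchoError(EchovolError):
    """The trace contains no detectable echo (e.g. an all-zero signal)."""


class NoPosteriorEchoError(EchovolError):
    """Fewer than two qualifying wall peaks: empty-bladder condition.

    Physically: with no urine the anterior wall reflects >99.9% of the
    pulse and the posterior wall is invisible. Recoverable — the channel
    simply contributes no wall points.
    """


class FitFailureError(EchovolError):
    """Nonlinear fit diverged or produced an invalid parameter vector."""


class InsufficientDataError(EchovolError):
    """Too few points to determine the quadric (need >= 9)."""


class RankDeficiencyError(EchovolError):
    """Degenerate point configuration (coplanar/coincident points)."""


class NonEllipsoidError(EchovolError):
    """The fitted quadric is not an ellipsoid."""


class PhantomConfigurationError(EchovolError):
    """Phantom geometry/config cannot produce a usable scan."""
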