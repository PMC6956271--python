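"""Exception hierarchy shared by all analysis stages."""


class OcunanoError(Exception):
    """Base class for all package errors."""


class DomainError(OcunanoError, ValueError):
    """An input violates a physical or mathematical precondition."""


class InsufficientDataError(OcunanoError, ValueError):
    """Too few data points to perform the requested fit or summary."""


class MassBalanceError(DomainError):
    """Assayed phase masses exceed the total drug load beyond tolerance."""


class InsufficientSignalError(OcunanoError, ValueError):
    """Correlogram signal is below the noise floor at every lag."""


class UnresolvedParticleError(OcunanoError, RuntimeError):
    """A particle profile cannot be resolved (below the optical limit)."""


class DegenerateTestError(OcunanoError, ValueError):
    """A statistical comparison has no variance to test against."""


class ConsistencyError(OcunanoError, ValueError):
    """Cross-stage labels or grids do not match."""
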