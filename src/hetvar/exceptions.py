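"""Exception hierarchy.

All numerical-failure errors derive from :class:`HetvarError` so callers
(notably the CLI) can distinguish method breakdown from user error, which
is signalled with the built-in ``ValueError``.
"""


class HetvarError(Exception):
    """Base class for numerical/internal failures."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (or numerically so)."""


class ConsistencyError(HetvarError):
    """An internal identity that must hold analytically failed numerically."""


class SpectralToleranceError(HetvarError):
    """Eigenvalue thresholding did not recover the expected rank."""


class ConvergenceError(HetvarError):
    """A root search failed to bracket or converge."""
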