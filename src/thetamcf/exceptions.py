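"""Exception and warning types used across the solver."""


class ThetaMCFError(Exception):
    """Base class for solver errors."""


class SingularOperatorError(ThetaMCFError):
    """A matrix that must be inverted is singular or hopelessly ill-conditioned."""


class ConvergenceError(ThetaMCFError):
    """A residual or self-consistency check exceeded its tolerance."""


class DegenerateFrequencyError(ThetaMCFError):
    """A harmonic combination k1*omega1 + k2*omega2 collides with zero.

    The cyclo-stationary operator L_0 + i*(k1*omega1 + k2*omega2) is singular
    at zero frequency offset; perturb one frequency to lift the degeneracy.
    """


class TruncationWarning(UserWarning):
    """The spectral truncation looks too low for the requested parameters."""
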