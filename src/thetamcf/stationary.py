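"""Stationary Fokker-Planck solution by the matrix-continued-fraction method.

Expanding the stationary density in Fourier modes (phase) and Hermite
functions (noise) turns the stationary Fokker-Planck equation into a
tridiagonal matrix recurrence for the coefficient vectors
``c_n = (c_{n,0}, c_{n,1}, ...)``:

    K_n c_n = c_{n-1} + c_{n+1},    K_n = 2 (B^{-1} - 1) - B^{-1} A / n,

with A the diagonal OU relaxation matrix and B the tridiagonal drift matrix.
The recurrence is closed from above by the matrix continued fraction:
transition matrices S_n defined by ``c_{n+1} = S_n c_n`` satisfy the backward
recursion ``S_{n-1} = (K_n - S_n)^{-1}``, initialized with S_{n_max} = 0.
Starting from the normalization vector ``c_0 = (1, 0, ...)`` all coefficients
follow, and the stationary firing rate is a linear combination of c_{1,0} and
c_{1,1}.  An independent rate estimate from the threshold value of the phase
density provides a built-in truncation check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._basis import build_A, build_B, hermite_psi
from .exceptions import ConvergenceError, SingularOperatorError, TruncationWarning
from .model import ModelParams

__all__ = [
    "TruncationSpec",
    "CoefficientSet",
    "build_A",
    "build_B",
    "build_K",
    "continued_fraction_S",
    "stationary_coefficients",
    "stationary_rate",
    "stationary_rate_with_check",
    "marginal_phase_density",
    "joint_density",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class TruncationSpec:
    """Spectral truncation: highest Fourier index n_max, highest Hermite index p_max.

    Note that at ``mu = 1`` the drift matrix B is exactly singular when
    ``p_max`` is even (its spectrum is symmetric around zero and has a zero
    eigenvalue in odd dimension); use an odd ``p_max`` there.
    """

    n_max: int = 150
    p_max: int = 150

    def __post_init__(self) -> None:
        if self.n_max < 1 or self.p_max < 1:
            raise ValueError("n_max and p_max must be >= 1")

    def scaled(self, factor: float) -> "TruncationSpec":
        """A proportionally enlarged truncation (used for convergence checks)."""
        return TruncationSpec(
            int(np.ceil(self.n_max * factor)), int(np.ceil(self.p_max * factor))
        )


class CoefficientSet:
    """Complex expansion coefficients c_{n,p} of a density-like function.

    Stores the full rectangle n in [-n_max, n_max], p in [0, p_max] as an
    array of shape (2*n_max+1, p_max+1).  For the stationary density the
    negative-n half is the complex conjugate of the positive half and
    c_{0,0} = 1 (normalization); members of the periodic-response hierarchy
    carry no such internal symmetry.
    """

    def __init__(self, coeffs: np.ndarray, params: ModelParams, trunc: TruncationSpec):
        coeffs = np.asarray(coeffs, dtype=complex)
        expected = (2 * trunc.n_max + 1, trunc.p_max + 1)
        if coeffs.shape != expected:
            raise ValueError(f"coefficient array must have shape {expected}, got {coeffs.shape}")
        self.coeffs = coeffs
        self.params = params
        self.trunc = trunc

    @property
    def n_max(self) -> int:
        return self.trunc.n_max

    @property
    def p_max(self) -> int:
        return self.trunc.p_max

    def get(self, n: int, p: int) -> complex:
        """Single coefficient c_{n,p}."""
        return complex(self.coeffs[n + self.n_max, p])

    def vector(self, n: int) -> np.ndarray:
        """Coefficient vector c_n over the Hermite index."""
        return self.coeffs[n + self.n_max]

    def conj_reflected(self) -> "CoefficientSet":
        """Coefficients of the complex conjugate function (n -> -n, conjugate)."""
        return CoefficientSet(np.conj(self.coeffs[::-1]), self.params, self.trunc)

    def threshold_eta_integral(self) -> complex:
        """integral d eta P(pi, eta) = sum_n (-1)^n c_{n,0} / (2 pi)."""
        signs = (-1.0) ** np.abs(np.arange(-self.n_max, self.n_max + 1))
        return complex(np.sum(signs * self.coeffs[:, 0]) / (2.0 * np.pi))

    def norm(self) -> float:
        return float(np.linalg.norm(self.coeffs))


def build_K(n: int, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Continued-fraction matrix K_n = 2 (B^{-1} - 1) - B^{-1} A / n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularOperatorError(
            f"B is singular or badly conditioned (cond={cond:.3g}); "
            "change p_max (e.g. its parity) to move its spectrum off zero"
        )
    Binv = np.linalg.inv(B)
    eye = np.eye(B.shape[0])
    return 2.0 * (Binv - eye) - Binv @ A / n


def continued_fraction_S(params: ModelParams, trunc: TruncationSpec) -> list[np.ndarray]:
    """Transition matrices S_0 .. S_{n_max-1} from the backward recursion.

    S_{n_max} = 0 truncates the continued fraction; then
    ``S_{n-1} = (K_n - S_n)^{-1}`` for n = n_max .. 1.
    """
    A = build_A(trunc.p_max, params.tau)
    B = build_B(trunc.p_max, params.mu, params.sigma)
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularOperatorError(
            f"B is singular or badly conditioned (cond={cond:.3g}); "
            "change p_max (e.g. its parity) to move its spectrum off zero"
        )
    Binv = np.linalg.inv(B)
    eye = np.eye(trunc.p_max + 1)
    BinvA = Binv @ A
    base = 2.0 * (Binv - eye)

    S = np.zeros((trunc.p_max + 1, trunc.p_max + 1), dtype=complex)
    out: list[np.ndarray] = [S] * trunc.n_max
    for n in range(trunc.n_max, 0, -1):
        K = base - BinvA / n
        M = K - S
        try:
            S = np.linalg.inv(M)
        except np.linalg.LinAlgError as exc:
            raise SingularOperatorError(
                f"singular matrix K_n - S_n encountered at n={n}; "
                "the configuration is degenerate (check tau, sigma and the truncation)"
            ) from exc
        if not np.all(np.isfinite(S)):
            raise SingularOperatorError(f"non-finite transition matrix at n={n}")
        out[n - 1] = S
    return out


def stationary_coefficients(params: ModelParams, trunc: TruncationSpec) -> CoefficientSet:
    """Full stationary coefficient set, c_{n+1} = S_n c_n from c_0 = (1,0,...).

    Negative-n coefficients are filled by conjugation (the stationary density
    is real).
    """
    S = continued_fraction_S(params, trunc)
    P = trunc.p_max + 1
    half = np.zeros((trunc.n_max + 1, P), dtype=complex)
    half[0, 0] = 1.0
    for n in range(trunc.n_max):
        half[n + 1] = S[n] @ half[n]
    full = np.zeros((2 * trunc.n_max + 1, P), dtype=complex)
    full[trunc.n_max:] = half
    full[: trunc.n_max] = np.conj(half[1:][::-1])
    return CoefficientSet(full, params, trunc)


def _rate_from_coefficients(c: CoefficientSet) -> float:
    """Stationary rate from the probability-current integral (uses c_{1,0}, c_{1,1})."""
    mu, sigma = c.params.mu, c.params.sigma
    return float(
        ((1.0 + mu) - (1.0 - mu) * c.get(1, 0).real + sigma * c.get(1, 1).real) / (2.0 * np.pi)
    )


def _rate_from_threshold(c: CoefficientSet) -> float:
    """Stationary rate from the threshold density, r = 2 * integral d eta P(pi, eta)."""
    return float(2.0 * c.threshold_eta_integral().real)


def stationary_rate_with_check(
    params: ModelParams, trunc: TruncationSpec | None = None
) -> tuple[float, float]:
    """Stationary rate via both independent formulas (current-based, threshold-based)."""
    trunc = trunc if trunc is not None else TruncationSpec()
    c = stationary_coefficients(params, trunc)
    return _rate_from_coefficients(c), _rate_from_threshold(c)


def stationary_rate(
    params: ModelParams,
    trunc: TruncationSpec | None = None,
    *,
    check_tol: float = 1e-6,
    strict: bool = False,
) -> float:
    """Stationary firing rate of the OU-driven theta neuron.

    Two independent evaluations are compared: the probability-current
    integral (a combination of c_{1,0} and c_{1,1}) and twice the
    eta-integrated density at the threshold phase (an alternating Fourier
    sum).  Their disagreement measures the truncation error.  The comparison
    uses an absolute floor of ``check_tol`` because in the weak-noise
    excitable regime the rate itself is numerically zero while the threshold
    Fourier sum converges slowly (the regime where the spectral method is
    known to degrade).

    With ``strict=True`` disagreement raises; by default it warns.
    """
    r_current, r_threshold = stationary_rate_with_check(params, trunc)
    scale = max(abs(r_current), abs(r_threshold), 1e-12)
    if abs(r_current - r_threshold) > check_tol * scale:
        msg = (
            f"rate cross-check failed: current-based {r_current:.8g} vs "
            f"threshold-based {r_threshold:.8g}; increase n_max/p_max "
            "(weak noise in the excitable regime and very long correlation "
            "times are outside the method's comfort zone)"
        )
        if strict:
            raise ConvergenceError(msg)
        warnings.warn(msg, TruncationWarning, stacklevel=2)
    return r_current


def marginal_phase_density(
    source: ModelParams | CoefficientSet,
    trunc: TruncationSpec | None = None,
    theta_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Marginal stationary phase density P_0(theta) on a grid in (-pi, pi].

    Only the p = 0 row of the coefficients enters:
    ``P_0(theta) = (1/2 pi) sum_n c_{n,0} e^{i n theta}``.  Values are real up
    to truncation ripple; a warning is issued if negativity exceeds 1e-6.
    """
    if theta_grid is None:
        raise ValueError("theta_grid is required")
    c = source if isinstance(source, CoefficientSet) else stationary_coefficients(
        source, trunc if trunc is not None else TruncationSpec()
    )
    theta = np.asarray(theta_grid, dtype=float)
    n = np.arange(-c.n_max, c.n_max + 1)
    phases = np.exp(1j * np.outer(theta, n))
    vals = (phases @ c.coeffs[:, 0]) / (2.0 * np.pi)
    out = vals.real
    if out.size and out.min() < -1e-6:
        warnings.warn(
            f"phase density negative down to {out.min():.3g}; truncation too low",
            TruncationWarning,
            stacklevel=2,
        )
    return out


def joint_density(
    source: ModelParams | CoefficientSet,
    trunc: TruncationSpec | None = None,
    theta_grid: np.ndarray | None = None,
    eta_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Joint stationary density P_0(theta, eta) on a tensor grid.

    Reconstruction includes the phi_0(eta) prefactor, i.e. rows of the result
    integrate to the marginal phase density and columns to the stationary OU
    Gaussian.  Shape: (len(theta_grid), len(eta_grid)).
    """
    if theta_grid is None or eta_grid is None:
        raise ValueError("theta_grid and eta_grid are required")
    c = source if isinstance(source, CoefficientSet) else stationary_coefficients(
        source, trunc if trunc is not None else TruncationSpec()
    )
    theta = np.asarray(theta_grid, dtype=float)
    eta = np.asarray(eta_grid, dtype=float)
    psi = hermite_psi(c.p_max, c.params.sigma, eta)  # (P, n_eta)
    n = np.arange(-c.n_max, c.n_max + 1)
    phases = np.exp(1j * np.outer(theta, n))  # (n_theta, Nn)
    vals = phases @ (c.coeffs @ psi) / (2.0 * np.pi)
    return vals.real
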