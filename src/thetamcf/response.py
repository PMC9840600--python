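"""Linear and nonlinear firing-rate response to one periodic signal.

Under a stimulus ``s(t) = epsilon*cos(omega*t)`` the density approaches a
cyclo-stationary state which is expanded in powers of epsilon and harmonics
of omega:

    P(theta, eta, t) = sum_{l>=0} sum_k epsilon^l e^{-i k omega t} P_{l,k}(theta, eta).

The members satisfy the iterative hierarchy

    (L_0 + i k omega) P_{l,k} = (1/2) L_per (P_{l-1,k-1} + P_{l-1,k+1}),

seeded by the stationary density P_{0,0}.  Members with |k| > l or with
k + l odd vanish identically, and P_{l,-k} is the complex conjugate (with
theta-Fourier reflection) of P_{l,k}, so only k >= 0 members are solved.

The firing rate follows from the threshold values of the members:

    r(t) = sum_{l} sum_{k=0}^{l} epsilon^l |r_{l,k}| cos(k omega t - phi_{l,k}),
    r_{l,k} = 2 (2 - delta_{k,0}) * integral d eta P_{l,k}(pi, eta).

``r_{1,1}(omega)`` is the susceptibility chi(omega); ``r_{2,0}`` is the
signal-induced shift of the time-averaged rate; ``r_{2,2}``, ``r_{3,3}`` ...
carry the higher harmonics, with resonances near the deterministic firing
frequency and its integer fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._linsys import apply_Lper, solve_member
from .exceptions import ThetaMCFError
from .model import ModelParams, SignalSpec
from .stationary import CoefficientSet, TruncationSpec, stationary_coefficients

__all__ = [
    "ResponseComponent",
    "ResponseHierarchy",
    "solve_hierarchy",
    "response_components",
    "susceptibility",
    "cyclostationary_rate",
]


@dataclass(frozen=True)
class ResponseComponent:
    """One term r_{l,k} of the rate expansion: order l, harmonic k, at frequency omega."""

    ell: int
    k: int
    omega: float
    value: complex

    @property
    def amplitude(self) -> float:
        return abs(self.value)

    @property
    def phase(self) -> float:
        """Complex argument in (-pi, pi], for the cos(k omega t - phi) convention."""
        return float(np.angle(self.value))


@dataclass
class ResponseHierarchy:
    """Solved hierarchy members P_{l,k} for one stimulus frequency.

    ``components`` maps (l, k) with k >= 0, k <= l, k + l even to the
    coefficient set of P_{l,k}; negative-k members follow by conjugation.
    """

    params: ModelParams
    signal: SignalSpec
    L_max: int
    trunc: TruncationSpec
    components: dict[tuple[int, int], CoefficientSet] = field(default_factory=dict)

    def member(self, ell: int, k: int) -> CoefficientSet | None:
        """P_{l,k} including negative k (conjugate-reflected); None if it vanishes."""
        if abs(k) > ell or (k + ell) % 2 != 0:
            return None
        if k >= 0:
            return self.components.get((ell, k))
        stored = self.components.get((ell, -k))
        return stored.conj_reflected() if stored is not None else None


def _rate_value(c: CoefficientSet, k_zero: bool) -> complex:
    factor = 2.0 * (2.0 - (1.0 if k_zero else 0.0))
    return factor * c.threshold_eta_integral()


def solve_hierarchy(
    params: ModelParams,
    signal: SignalSpec,
    L_max: int,
    trunc: TruncationSpec | None = None,
    *,
    resid_tol: float = 1e-9,
) -> ResponseHierarchy:
    """Solve the cyclo-stationary hierarchy up to order epsilon^L_max.

    The signal amplitude does not enter the member equations (epsilon is the
    expansion parameter and reappears only in the rate reconstruction), so
    the hierarchy can be reused for any amplitude at this frequency.
    """
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    trunc = trunc if trunc is not None else TruncationSpec()
    omega = signal.omega
    h = ResponseHierarchy(params=params, signal=signal, L_max=L_max, trunc=trunc)
    h.components[(0, 0)] = stationary_coefficients(params, trunc)

    zeros = np.zeros_like(h.components[(0, 0)].coeffs)
    for ell in range(1, L_max + 1):
        for k in range(ell % 2, ell + 1, 2):
            prev_lo = h.member(ell - 1, k - 1)
            prev_hi = h.member(ell - 1, k + 1)
            forcing = zeros.copy()
            if prev_lo is not None:
                forcing += prev_lo.coeffs
            if prev_hi is not None:
                forcing += prev_hi.coeffs
            rhs = 0.5 * apply_Lper(forcing)
            try:
                sol = solve_member(
                    params, trunc, k * omega, rhs, resid_tol=resid_tol, label=f"(l={ell}, k={k})"
                )
            except ThetaMCFError as exc:
                raise type(exc)(f"{exc} [l={ell}, k={k}, omega={omega}]") from exc
            h.components[(ell, k)] = CoefficientSet(sol, params, trunc)
    return h


def response_components(h: ResponseHierarchy) -> list[ResponseComponent]:
    """Rate-expansion terms r_{l,k} for every solved member (k >= 0)."""
    out = []
    for (ell, k), c in sorted(h.components.items()):
        out.append(
            ResponseComponent(ell=ell, k=k, omega=h.signal.omega, value=_rate_value(c, k == 0))
        )
    return out


def susceptibility(
    params: ModelParams, omega: float, trunc: TruncationSpec | None = None
) -> complex:
    """Linear response coefficient chi(omega) = r_{1,1}(omega) as a complex number."""
    h = solve_hierarchy(params, SignalSpec(epsilon=1.0, omega=omega), L_max=1, trunc=trunc)
    return _rate_value(h.components[(1, 1)], k_zero=False)


def cyclostationary_rate(
    components: Sequence[ResponseComponent] | Mapping[tuple[int, int], complex],
    epsilon: float,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Reconstruct r(t) from response components at amplitude epsilon.

    Sums ``epsilon^l |r_{l,k}| cos(k omega t - phi_{l,k})`` over the supplied
    components.  The result is periodic with the stimulus period; a warning
    is issued when the truncated series dips below zero (amplitude outside
    the validity of the retained orders).
    """
    t = np.asarray(time_grid, dtype=float)
    if isinstance(components, Mapping):
        raise TypeError("pass the list returned by response_components()")
    out = np.zeros_like(t)
    for comp in components:
        term = (
            epsilon**comp.ell
            * comp.amplitude
            * np.cos(comp.k * comp.omega * t - comp.phase)
        )
        if comp.k == 0:
            # zero-harmonic terms are real constants (phase 0 or pi)
            term = epsilon**comp.ell * comp.value.real * np.ones_like(t)
        out += term
    if out.size and out.min() < 0:
        warnings.warn(
            f"reconstructed rate negative (min {out.min():.3g}); "
            "epsilon too large for the truncated expansion order",
            UserWarning,
            stacklevel=2,
        )
    return out
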