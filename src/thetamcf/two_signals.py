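"""Second-order firing-rate response to two periodic signals.

For ``s(t) = eps1*cos(omega1 t) + eps2*cos(omega2 t)`` (frequencies in
general incommensurable) the density is expanded in powers of both
amplitudes and in the joint harmonics ``e^{-i (k1 omega1 + k2 omega2) t}``.
The hierarchy members P^{l1,l2}_{k1,k2} with l1 + l2 <= 2 are:

    order 0:  P^{0,0}_{0,0}  (the stationary density)
    order 1:  P^{1,0}_{1,0}, P^{0,1}_{0,1}
    order 2:  P^{2,0}_{2,0}, P^{0,2}_{0,2}, P^{2,0}_{0,0}, P^{0,2}_{0,0},
              P^{1,1}_{1,1}, P^{1,1}_{1,-1}

each solving (L_0 + i(k1 omega1 + k2 omega2)) P = (1/2) L_per (sum of
lower-order members).  The members with l2 = 0 coincide with the
single-signal hierarchy at omega1 (and vice versa).  The mixed members
P^{1,1}_{1,+-1} describe the interaction of the two signals; their rate
amplitudes resonate when |omega1 +- omega2| matches the deterministic firing
frequency 2*pi*r_det.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linsys import apply_Lper, solve_member
from .exceptions import DegenerateFrequencyError, ThetaMCFError
from .model import ModelParams, SignalSpec
from .stationary import CoefficientSet, TruncationSpec, stationary_coefficients

__all__ = [
    "TwoSignalComponent",
    "TwoSignalHierarchy",
    "solve_two_signal_hierarchy",
    "two_signal_components",
    "two_signal_rate",
    "mixed_response_scan",
]

# (l1, l2, k1, k2) in solve order; forcing terms are pairs of
# (member key or None, conjugate?) referring to previously solved members.
_MEMBERS: list[tuple[tuple[int, int, int, int], list[tuple[tuple[int, int, int, int], bool]]]] = [
    ((1, 0, 1, 0), [((0, 0, 0, 0), False)]),
    ((0, 1, 0, 1), [((0, 0, 0, 0), False)]),
    ((2, 0, 2, 0), [((1, 0, 1, 0), False)]),
    ((0, 2, 0, 2), [((0, 1, 0, 1), False)]),
    ((2, 0, 0, 0), [((1, 0, 1, 0), False), ((1, 0, 1, 0), True)]),
    ((0, 2, 0, 0), [((0, 1, 0, 1), False), ((0, 1, 0, 1), True)]),
    ((1, 1, 1, 1), [((1, 0, 1, 0), False), ((0, 1, 0, 1), False)]),
    ((1, 1, 1, -1), [((1, 0, 1, 0), False), ((0, 1, 0, 1), True)]),
]

_DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class TwoSignalComponent:
    """One term r^{l1,l2}_{k1,k2} of the two-signal rate expansion."""

    l1: int
    l2: int
    k1: int
    k2: int
    omega1: float
    omega2: float
    value: complex

    @property
    def amplitude(self) -> float:
        return abs(self.value)

    @property
    def phase(self) -> float:
        return float(np.angle(self.value))

    @property
    def frequency(self) -> float:
        """Combination frequency k1*omega1 + k2*omega2 of this term."""
        return self.k1 * self.omega1 + self.k2 * self.omega2


@dataclass
class TwoSignalHierarchy:
    """Solved members P^{l1,l2}_{k1,k2} with l1 + l2 <= 2."""

    params: ModelParams
    s1: SignalSpec
    s2: SignalSpec
    trunc: TruncationSpec
    components: dict[tuple[int, int, int, int], CoefficientSet] = field(default_factory=dict)

    def member(self, l1: int, l2: int, k1: int, k2: int) -> CoefficientSet | None:
        """Member including conjugate-reflected (-k1, -k2) partners."""
        key = (l1, l2, k1, k2)
        if key in self.components:
            return self.components[key]
        mirror = (l1, l2, -k1, -k2)
        if mirror in self.components:
            return self.components[mirror].conj_reflected()
        return None


def solve_two_signal_hierarchy(
    params: ModelParams,
    s1: SignalSpec,
    s2: SignalSpec,
    trunc: TruncationSpec | None = None,
    *,
    resid_tol: float = 1e-9,
) -> TwoSignalHierarchy:
    """Solve the two-signal hierarchy to second order in both amplitudes.

    Raises :class:`DegenerateFrequencyError` when a required harmonic
    combination k1*omega1 + k2*omega2 vanishes for (k1, k2) != (0, 0) --
    e.g. omega1 = omega2, which makes the difference member singular.
    """
    trunc = trunc if trunc is not None else TruncationSpec()
    om1, om2 = s1.omega, s2.omega
    for (l1, l2, k1, k2), _ in _MEMBERS:
        shift = k1 * om1 + k2 * om2
        if (k1, k2) != (0, 0) and abs(shift) < _DEGENERACY_TOL:
            raise DegenerateFrequencyError(
                f"harmonic combination k1*omega1 + k2*omega2 = {shift:.3g} for member "
                f"(l1={l1}, l2={l2}, k1={k1}, k2={k2}); perturb one frequency"
            )

    h = TwoSignalHierarchy(params=params, s1=s1, s2=s2, trunc=trunc)
    h.components[(0, 0, 0, 0)] = stationary_coefficients(params, trunc)
    for key, forcing_spec in _MEMBERS:
        l1, l2, k1, k2 = key
        forcing = np.zeros_like(h.components[(0, 0, 0, 0)].coeffs)
        for src_key, conjugate in forcing_spec:
            src = h.components[src_key]
            forcing += (src.conj_reflected() if conjugate else src).coeffs
        rhs = 0.5 * apply_Lper(forcing)
        shift = k1 * om1 + k2 * om2
        try:
            sol = solve_member(params, trunc, shift, rhs, resid_tol=resid_tol, label=str(key))
        except ThetaMCFError as exc:
            raise type(exc)(f"{exc} [member {key}, omega1={om1}, omega2={om2}]") from exc
        h.components[key] = CoefficientSet(sol, params, trunc)
    return h


def two_signal_components(h: TwoSignalHierarchy) -> list[TwoSignalComponent]:
    """Rate-expansion terms r^{l1,l2}_{k1,k2} for all solved members."""
    out = []
    for (l1, l2, k1, k2), c in h.components.items():
        factor = 2.0 * (2.0 - (1.0 if (k1, k2) == (0, 0) else 0.0))
        out.append(
            TwoSignalComponent(
                l1=l1,
                l2=l2,
                k1=k1,
                k2=k2,
                omega1=h.s1.omega,
                omega2=h.s2.omega,
                value=factor * c.threshold_eta_integral(),
            )
        )
    return out


def two_signal_rate(
    h: TwoSignalHierarchy,
    eps1: float,
    eps2: float,
    time_grid: np.ndarray,
    *,
    include_mixed: bool = True,
) -> np.ndarray:
    """Second-order rate r(t) under both signals.

    With ``include_mixed=False`` the interaction terms (l1 = l2 = 1) are
    dropped, which equals the sum of the single-signal second-order
    responses (the stationary baseline counted once).
    """
    t = np.asarray(time_grid, dtype=float)
    out = np.zeros_like(t)
    for comp in two_signal_components(h):
        if not include_mixed and comp.l1 == 1 and comp.l2 == 1:
            continue
        weight = eps1**comp.l1 * eps2**comp.l2
        if (comp.k1, comp.k2) == (0, 0):
            out += weight * comp.value.real
        else:
            out += weight * comp.amplitude * np.cos(comp.frequency * t - comp.phase)
    if out.size and out.min() < 0:
        warnings.warn(
            f"reconstructed two-signal rate negative (min {out.min():.3g}); "
            "amplitudes outside perturbative validity",
            UserWarning,
            stacklevel=2,
        )
    return out


def mixed_response_scan(
    params: ModelParams,
    omega1_grid: np.ndarray,
    omega2_grid: np.ndarray,
    trunc: TruncationSpec | None = None,
) -> pd.DataFrame:
    """All second-order response amplitudes/phases over a frequency grid.

    Returns a tidy table with one row per (omega1, omega2, member); points
    where the solve fails (e.g. degenerate harmonic combinations) are
    recorded with status != 'ok' and NaN amplitudes, and the scan continues.
    """
    rows = []
    for om1 in np.asarray(omega1_grid, dtype=float):
        for om2 in np.asarray(omega2_grid, dtype=float):
            try:
                h = solve_two_signal_hierarchy(
                    params, SignalSpec(1.0, om1), SignalSpec(1.0, om2), trunc
                )
            except ThetaMCFError as exc:
                rows.append(
                    dict(
                        mu=params.mu, sigma=params.sigma, tau=params.tau,
                        omega1=om1, omega2=om2, l1=np.nan, l2=np.nan,
                        k1=np.nan, k2=np.nan, amplitude=np.nan, phase=np.nan,
                        status=type(exc).__name__,
                    )
                )
                continue
            for comp in two_signal_components(h):
                if (comp.l1, comp.l2) == (0, 0):
                    continue
                rows.append(
                    dict(
                        mu=params.mu, sigma=params.sigma, tau=params.tau,
                        omega1=om1, omega2=om2, l1=comp.l1, l2=comp.l2,
                        k1=comp.k1, k2=comp.k2, amplitude=comp.amplitude,
                        phase=comp.phase, status="ok",
                    )
                )
    return pd.DataFrame(rows)
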