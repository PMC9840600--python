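"""Theta-neuron model definitions, parameter scalings and closed-form rate limits.

The theta neuron is the phase representation of the quadratic
integrate-and-fire neuron (``x = tan(theta/2)``),

    dtheta/dt = (1 - cos theta) + (1 + cos theta) * I(t),

with input ``I(t) = mu + eta(t) + s(t)``: a constant mean drive ``mu``, an
Ornstein-Uhlenbeck (OU) noise ``eta`` with autocorrelation
``sigma^2 * exp(-dt/tau)``, and an optional periodic signal
``s(t) = epsilon*cos(omega*t)``.  A spike is registered whenever the phase
passes ``theta = pi``; no reset rule is needed because the phase simply wraps.

All times are measured in units of the membrane time constant, so rates are
dimensionless (multiples of the inverse membrane time).  To convert a rate to
Hz divide by the membrane time constant in seconds.

This module holds the parameter containers, the exact parameter rescalings
that reduce the (mu, sigma, tau) space to two parameters, and the closed-form
limits (deterministic rate, quasi-static average, weak-noise correction,
low/high-frequency susceptibility) that serve as references for the
spectral solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.integrate import quad

from .exceptions import ConvergenceError

__all__ = [
    "ModelParams",
    "SignalSpec",
    "phase_velocity",
    "deterministic_rate",
    "quasi_static_rate",
    "galan_rate",
    "rescale_constant_variance",
    "undo_constant_variance",
    "rescale_constant_intensity",
    "undo_constant_intensity",
    "high_freq_susceptibility",
    "low_freq_susceptibility",
]

_SCALINGS = ("raw", "constant_variance", "constant_intensity")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the noise-driven theta neuron.

    Parameters
    ----------
    mu
        Mean input; ``mu < 0`` is the excitable regime, ``mu > 0`` mean-driven.
    sigma
        Standard deviation of the OU noise (dimensionless input units).
    tau
        Noise correlation time over membrane time constant; ``tau -> 0`` with
        fixed ``sigma`` removes the noise, while fixing ``D = sigma^2 * tau``
        yields a nontrivial white-noise limit.
    scaling
        Bookkeeping tag: 'raw', 'constant_variance' (sigma held fixed) or
        'constant_intensity' (D held fixed).
    """

    mu: float
    sigma: float
    tau: float
    scaling: str = "raw"

    def __post_init__(self) -> None:
        if not self.sigma >= 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.scaling not in _SCALINGS:
            raise ValueError(f"scaling must be one of {_SCALINGS}, got {self.scaling!r}")

    @property
    def D(self) -> float:
        """Noise intensity D = sigma^2 * tau."""
        return self.sigma**2 * self.tau


@dataclass(frozen=True)
class SignalSpec:
    """One cosine stimulus ``s(t) = epsilon * cos(omega * t)``."""

    epsilon: float
    omega: float

    def __post_init__(self) -> None:
        if not self.epsilon >= 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")

    def __call__(self, t):
        return self.epsilon * np.cos(self.omega * np.asarray(t))


def phase_velocity(theta, eta, s, mu):
    """Phase velocity f(theta, eta, s) of the theta neuron.

    ``f = (1 - cos theta) + (1 + cos theta)(mu + eta + s)``.  At the spike
    threshold ``theta = pi`` the velocity equals 2 independently of the input,
    which is what ties the firing rate to the threshold density.
    """
    theta = np.asarray(theta, dtype=float)
    return (1.0 - np.cos(theta)) + (1.0 + np.cos(theta)) * (mu + eta + s)


def deterministic_rate(mu):
    """Firing rate of the noise-free theta neuron: sqrt(mu)/pi for mu > 0, else 0."""
    mu = np.asarray(mu, dtype=float)
    out = np.where(mu > 0, np.sqrt(np.clip(mu, 0.0, None)) / np.pi, 0.0)
    return out if out.ndim else float(out)


def quasi_static_rate(mu: float, sigma: float, rtol: float = 1e-10) -> float:
    """Long-correlation-time (quasi-static) rate limit.

    For ``tau -> infinity`` the OU noise acts as a frozen Gaussian offset of
    the mean input, so the rate is the Gaussian average of the deterministic
    rate::

        r_inf(mu) = E_I[ r_det(I) ],   I ~ N(mu, sigma^2).

    Computed by adaptive quadrature on the half line I > 0 where the
    integrand is supported.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")

    def integrand(i: float) -> float:
        return (
            math.sqrt(i)
            / math.pi
            * math.exp(-((i - mu) ** 2) / (2.0 * sigma**2))
            / (sigma * math.sqrt(2.0 * math.pi))
        )

    upper = max(mu, 0.0) + 12.0 * sigma
    if upper <= 0:
        return 0.0
    val, err = quad(integrand, 0.0, upper, epsrel=rtol, epsabs=0.0, limit=200)
    if val > 0 and err > 1e-8 * max(val, 1e-12):
        raise ConvergenceError(
            f"quasi-static quadrature did not converge: value={val}, error estimate={err}"
        )
    return val


def galan_rate(mu: float, sigma: float, tau: float) -> float:
    """Weak-noise phase-response-curve approximation of the stationary rate.

    Valid in the strongly mean-driven regime (sigma << mu)::

        r0 ~ r_det - (sigma^2 / 2 pi) * (tau^2 / sqrt(mu)) / (4 mu tau^2 + 1).

    It predicts a monotone decrease of the rate with correlation time.
    """
    if not mu > 0:
        raise ValueError("galan_rate requires mu > 0 (mean-driven regime)")
    correction = (sigma**2 / (2.0 * math.pi)) * (tau**2 / math.sqrt(mu)) / (4.0 * mu * tau**2 + 1.0)
    return float(deterministic_rate(mu)) - correction


def _as_signal_tuple(signals: Iterable[SignalSpec] | None) -> tuple[SignalSpec, ...]:
    return tuple(signals) if signals is not None else ()


def rescale_constant_variance(
    p: ModelParams, signals: Iterable[SignalSpec] | None = None
) -> tuple[ModelParams, tuple[SignalSpec, ...], float]:
    """Map (mu, sigma, tau) onto the sigma = 1 slice of parameter space.

    Returns the rescaled parameters ``(mu/sigma, 1, sqrt(sigma)*tau)``,
    rescaled signals ``(eps/sigma, omega/sqrt(sigma))`` and the rate factor
    ``sqrt(sigma)`` such that ``r = sqrt(sigma) * r_hat``.
    """
    if not p.sigma > 0:
        raise ValueError("constant-variance rescaling requires sigma > 0")
    s = p.sigma
    new_p = replace(p, mu=p.mu / s, sigma=1.0, tau=math.sqrt(s) * p.tau, scaling="constant_variance")
    new_signals = tuple(
        SignalSpec(sig.epsilon / s, sig.omega / math.sqrt(s)) for sig in _as_signal_tuple(signals)
    )
    return new_p, new_signals, math.sqrt(s)


def undo_constant_variance(
    p_hat: ModelParams, signals: Iterable[SignalSpec] | None, rate_factor: float
) -> tuple[ModelParams, tuple[SignalSpec, ...]]:
    """Invert :func:`rescale_constant_variance` given its rate factor."""
    s = rate_factor**2
    orig = replace(p_hat, mu=p_hat.mu * s, sigma=s, tau=p_hat.tau / math.sqrt(s), scaling="raw")
    orig_signals = tuple(
        SignalSpec(sig.epsilon * s, sig.omega * math.sqrt(s)) for sig in _as_signal_tuple(signals)
    )
    return orig, orig_signals


def rescale_constant_intensity(
    p: ModelParams, signals: Iterable[SignalSpec] | None = None
) -> tuple[ModelParams, tuple[SignalSpec, ...], float]:
    """Map (mu, sigma, tau) onto the D = 1 slice of parameter space.

    Returns ``(mu/D^(2/3), sigma', D^(1/3)*tau)`` with ``sigma'`` chosen so
    that the rescaled intensity is one, rescaled signals
    ``(eps/D^(2/3), omega/D^(1/3))`` and the rate factor ``D^(1/3)`` such
    that ``r = D^(1/3) * r_tilde``.
    """
    D = p.D
    if not D > 0:
        raise ValueError("constant-intensity rescaling requires D = sigma^2 * tau > 0")
    new_tau = D ** (1.0 / 3.0) * p.tau
    new_sigma = math.sqrt(1.0 / new_tau)  # intensity sigma'^2 * tau' = 1
    new_p = replace(
        p, mu=p.mu / D ** (2.0 / 3.0), sigma=new_sigma, tau=new_tau, scaling="constant_intensity"
    )
    new_signals = tuple(
        SignalSpec(sig.epsilon / D ** (2.0 / 3.0), sig.omega / D ** (1.0 / 3.0))
        for sig in _as_signal_tuple(signals)
    )
    return new_p, new_signals, D ** (1.0 / 3.0)


def undo_constant_intensity(
    p_tilde: ModelParams, signals: Iterable[SignalSpec] | None, rate_factor: float
) -> tuple[ModelParams, tuple[SignalSpec, ...]]:
    """Invert :func:`rescale_constant_intensity` given its rate factor."""
    D = rate_factor**3
    tau = p_tilde.tau / D ** (1.0 / 3.0)
    sigma = math.sqrt(D / tau)
    orig = replace(p_tilde, mu=p_tilde.mu * D ** (2.0 / 3.0), sigma=sigma, tau=tau, scaling="raw")
    orig_signals = tuple(
        SignalSpec(sig.epsilon * D ** (2.0 / 3.0), sig.omega * D ** (1.0 / 3.0))
        for sig in _as_signal_tuple(signals)
    )
    return orig, orig_signals


def high_freq_susceptibility(r0: float, omega: float) -> tuple[float, float]:
    """High-frequency limit of the linear response: (|chi|, phase) = (2 r0/omega^2, pi)."""
    if not omega > 0:
        raise ValueError("omega must be > 0")
    return 2.0 * r0 / omega**2, math.pi


def low_freq_susceptibility(p: ModelParams, trunc=None, dmu: float = 1e-3) -> float:
    """Zero-frequency limit of the susceptibility, |chi(0)| = d r0 / d mu.

    Central finite difference of the stationary spectral rate over mu +- dmu.
    """
    if not dmu > 0:
        raise ValueError("dmu must be > 0")
    from .stationary import TruncationSpec, stationary_rate

    trunc = trunc if trunc is not None else TruncationSpec()
    r_plus = stationary_rate(replace(p, mu=p.mu + dmu), trunc)
    r_minus = stationary_rate(replace(p, mu=p.mu - dmu), trunc)
    return (r_plus - r_minus) / (2.0 * dmu)
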