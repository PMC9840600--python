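"""Fourier x Hermite spectral basis for the (theta, eta) Fokker-Planck problem.

The joint density is expanded as

    P(theta, eta) = phi_0(eta)/(2 pi) * sum_{n,p} c_{n,p} e^{i n theta} phi_p(eta),

where phi_p are the orthonormal Hermite eigenfunctions of the OU
Fokker-Planck operator: phi_0^2 is the stationary Gaussian of variance
sigma^2, L_OU (phi_0 phi_p) = -(p/tau) phi_0 phi_p, and the ladder relation

    eta * phi_p = sigma * (sqrt(p+1) phi_{p+1} + sqrt(p) phi_{p-1})

turns multiplication by eta into the symmetric tridiagonal matrix built here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ladder_matrix", "build_A", "build_B", "hermite_psi"]


def ladder_matrix(p_max: int, sigma: float) -> np.ndarray:
    """Matrix of multiplication by eta in the Hermite basis (symmetric tridiagonal)."""
    P = p_max + 1
    off = sigma * np.sqrt(np.arange(1, P))
    H = np.zeros((P, P))
    H[np.arange(P - 1), np.arange(1, P)] = off
    H[np.arange(1, P), np.arange(P - 1)] = off
    return H


def build_A(p_max: int, tau: float) -> np.ndarray:
    """Diagonal matrix i*q/tau of OU relaxation rates, q = 0..p_max."""
    if not tau > 0:
        raise ValueError("tau must be > 0")
    return np.diag(1j * np.arange(p_max + 1) / tau)


def build_B(p_max: int, mu: float, sigma: float) -> np.ndarray:
    """Real symmetric tridiagonal matrix B = ((1 - mu) I - eta-ladder)/2.

    Diagonal entries (1 - mu)/2; the entry coupling Hermite orders p and p+1
    is -(sigma/2) sqrt(p+1).  B represents half the cos(theta) part of the
    drift, (1 - mu - eta)/2, in the Hermite basis.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    P = p_max + 1
    return ((1.0 - mu) * np.eye(P) - ladder_matrix(p_max, sigma)) / 2.0


def hermite_psi(p_max: int, sigma: float, eta: np.ndarray) -> np.ndarray:
    """Evaluate psi_p(eta) = phi_0(eta) * phi_p(eta) for p = 0..p_max.

    psi_0 is the stationary OU Gaussian N(0, sigma^2); higher psi_p are the
    Gaussian times normalized probabilists' Hermite polynomials
    He_p(eta/sigma)/sqrt(p!), computed by the stable three-term recurrence.
    Returns an array of shape (p_max+1, len(eta)).
    """
    eta = np.asarray(eta, dtype=float)
    x = eta / sigma
    out = np.empty((p_max + 1, eta.size))
    gauss = np.exp(-(eta**2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2.0 * np.pi))
    out[0] = 1.0
    if p_max >= 1:
        out[1] = x
    for p in range(1, p_max):
        out[p + 1] = (x * out[p] - np.sqrt(p) * out[p - 1]) / np.sqrt(p + 1)
    return out * gauss
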