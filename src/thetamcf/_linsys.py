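"""Banded linear algebra for the cyclo-stationary hierarchy.

Each member P_{l,k} of the response hierarchy solves an inhomogeneous
equation (L_0 + i*Omega) P = RHS, where Omega is the harmonic frequency
offset.  In the Fourier x Hermite coefficient space the operator acts
block-tridiagonally over the Fourier index m (with blocks tridiagonal over
the Hermite index p):

    (L_0 c)_m = [-i m ((1+mu) I + H) - N/tau] c_m + i m B (c_{m-1} + c_{m+1}),

with H the eta-ladder matrix, N = diag(p) and B = ((1-mu) I - H)/2.  The
periodic forcing operator L_per = d/dtheta (1 + cos theta) is the spectral
multiplication

    (L_per c)_m = i m [c_m + (c_{m-1} + c_{m+1})/2].

The full system over n in [-n_max, n_max] is assembled in LAPACK band
storage (bandwidth p_max + 2 on each side) and solved directly.  For a zero
frequency offset the operator is singular (the stationary density spans its
null space); the (n=0, p=0) row is then replaced by the normalization
constraint c_{0,0} = 0 valid for every correction term.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from .exceptions import ConvergenceError, SingularOperatorError
from .model import ModelParams
from .stationary import TruncationSpec

__all__ = ["apply_L", "apply_Lper", "solve_member"]


def apply_Lper(c: np.ndarray) -> np.ndarray:
    """Apply the periodic forcing operator to a coefficient array (Nn, P)."""
    n_max = (c.shape[0] - 1) // 2
    ns = np.arange(-n_max, n_max + 1)
    neighbours = np.zeros_like(c)
    neighbours[1:] += c[:-1]
    neighbours[:-1] += c[1:]
    return 1j * ns[:, None] * (c + neighbours / 2.0)


def apply_L(c: np.ndarray, params: ModelParams, shift: float) -> np.ndarray:
    """Apply L_0 + i*shift to a coefficient array (Nn, P) without assembling it."""
    n_max = (c.shape[0] - 1) // 2
    P = c.shape[1]
    mu, sigma, tau = params.mu, params.sigma, params.tau
    ns = np.arange(-n_max, n_max + 1)[:, None]
    ps = np.arange(P)[None, :]
    off = sigma * np.sqrt(np.arange(1, P))

    def ladder(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        out[:, :-1] += off * x[:, 1:]
        out[:, 1:] += off * x[:, :-1]
        return out

    neighbours = np.zeros_like(c)
    neighbours[1:] += c[:-1]
    neighbours[:-1] += c[1:]
    malpha = (1.0 + mu) * c + ladder(c)
    bterm = ((1.0 - mu) * neighbours - ladder(neighbours)) / 2.0
    return -1j * ns * malpha - (ps / tau) * c + 1j * shift * c + 1j * ns * bterm


def _assemble_banded(params: ModelParams, trunc: TruncationSpec, shift: float):
    """LAPACK band storage of L_0 + i*shift over the flattened (n, p) index."""
    n_max, p_max = trunc.n_max, trunc.p_max
    P = p_max + 1
    Nn = 2 * n_max + 1
    N = Nn * P
    mu, sigma, tau = params.mu, params.sigma, params.tau
    l = u = P + 1
    ab = np.zeros((l + u + 1, N), dtype=complex)

    ns = np.arange(-n_max, n_max + 1)
    ps = np.arange(P)
    n_flat = np.repeat(ns, P).astype(float)
    p_flat = np.tile(ps, Nn).astype(float)
    sqrt_up = np.sqrt(p_flat + 1.0)  # ladder entry to p+1
    sqrt_dn = np.sqrt(p_flat)  # ladder entry to p-1

    # column-block boundary masks for Hermite offsets
    p_not_last = p_flat < p_max
    p_not_first = p_flat > 0

    def place(offset: int, values: np.ndarray) -> None:
        # matrix entry M[i, i+offset] = values[i]; band row u - offset
        if offset >= 0:
            ab[u - offset, offset:] += values[: N - offset]
        else:
            ab[u - offset, : N + offset] += values[-offset:]

    # diagonal block (dn = 0)
    place(0, -1j * n_flat * (1.0 + mu) - p_flat / tau + 1j * shift)
    place(1, np.where(p_not_last, -1j * n_flat * sigma * sqrt_up, 0.0))
    place(-1, np.where(p_not_first, -1j * n_flat * sigma * sqrt_dn, 0.0))

    # neighbour blocks (dn = +-1): i * n * B
    for dn in (-1, 1):
        base = dn * P
        place(base, 1j * n_flat * (1.0 - mu) / 2.0)
        place(base + 1, np.where(p_not_last, 1j * n_flat * (-sigma / 2.0) * sqrt_up, 0.0))
        place(base - 1, np.where(p_not_first, 1j * n_flat * (-sigma / 2.0) * sqrt_dn, 0.0))

    return ab, l, u


def solve_member(
    params: ModelParams,
    trunc: TruncationSpec,
    shift: float,
    rhs: np.ndarray,
    *,
    normalize: bool | None = None,
    resid_tol: float = 1e-9,
    label: str = "",
) -> np.ndarray:
    """Solve (L_0 + i*shift) x = rhs for one hierarchy member.

    ``normalize`` replaces the (0,0) row by the constraint c_{0,0} = 0; by
    default it is applied exactly when shift == 0 (singular operator).  The
    solution's residual is verified against ``resid_tol`` relative to the
    forcing magnitude.
    """
    n_max, p_max = trunc.n_max, trunc.p_max
    P = p_max + 1
    if normalize is None:
        normalize = shift == 0.0
    ab, l, u = _assemble_banded(params, trunc, shift)
    b = rhs.ravel().astype(complex).copy()
    N = b.size
    row = n_max * P  # flattened (n=0, p=0)
    if normalize:
        js = np.arange(max(0, row - l), min(N, row + u + 1))
        ab[u + row - js, js] = 0.0
        ab[u, row] = 1.0
        b[row] = 0.0
    try:
        x = solve_banded((l, u), ab, b, overwrite_ab=True, overwrite_b=True)
    except np.linalg.LinAlgError as exc:
        raise SingularOperatorError(
            f"singular cyclo-stationary operator for member {label or '?'} "
            f"(frequency offset {shift}); a truncation artifact resonance or a "
            "degenerate harmonic combination"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise SingularOperatorError(f"non-finite solution for member {label or '?'}")
    x = x.reshape(rhs.shape)

    resid = apply_L(x, params, shift) - rhs
    if normalize:
        resid[n_max, 0] = x[n_max, 0]  # constraint row: must be zero itself
    scale = max(float(np.max(np.abs(rhs))), 1.0)
    worst = float(np.max(np.abs(resid)))
    if worst > resid_tol * scale:
        raise ConvergenceError(
            f"linear-system residual {worst:.3g} exceeds {resid_tol:.1g} x {scale:.3g} "
            f"for member {label or '?'} (frequency offset {shift})"
        )
    return x
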