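"""Euler-Maruyama spike-train simulator: the package's Monte-Carlo ground truth.

Integrates the Langevin system

    dtheta/dt = (1 - cos theta) + (1 + cos theta) (mu + eta + s(t)),
    tau deta/dt = -eta + sqrt(2 tau sigma^2) xi(t),

recording a spike whenever the phase crosses pi (detected by sign change
with linear interpolation of the crossing time) and wrapping the phase by
2 pi.  The noise channel uses the exact OU transition by default, which
removes the time-step bias from the noise; a plain Euler-Maruyama mode for
eta is available as well.  Each trial has its own counter-derived random
stream, so ensembles are reproducible bit-for-bit regardless of chunking.

Estimators turn spike ensembles into the quantities the spectral solver
computes: the stationary rate, the trial-averaged instantaneous rate (PSTH),
and complex harmonic amplitudes of the cyclo-stationary rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ModelParams, SignalSpec

__all__ = [
    "SimSettings",
    "SpikeEnsemble",
    "RateEstimate",
    "simulate",
    "sample_ou",
    "estimate_stationary_rate",
    "estimate_rate_psth",
    "estimate_harmonics",
]

_CHUNK_STEPS = 2000


@dataclass(frozen=True)
class SimSettings:
    """Integration settings.

    Defaults use the reference time step dt = 5e-3 (units of the membrane
    time constant).  ``initial_state`` 'stationary' draws eta from its
    stationary Gaussian and the phase uniformly, to be combined with a
    transient ``t_transient`` that estimators discard; 'reset' starts every
    trial at (theta, eta) = (-pi, 0) for transient studies.
    """

    dt: float = 5e-3
    T: float = 500.0
    n_trials: int = 100
    seed: int = 0
    t_transient: float = 0.0
    initial_state: str = "stationary"
    ou_update: str = "exact"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not (self.T > self.t_transient >= 0):
            raise ValueError("need T > t_transient >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.initial_state not in ("stationary", "reset"):
            raise ValueError("initial_state must be 'stationary' or 'reset'")
        if self.ou_update not in ("exact", "euler"):
            raise ValueError("ou_update must be 'exact' or 'euler'")


@dataclass
class SpikeEnsemble:
    """Per-trial ordered spike times plus everything needed to regenerate them."""

    spike_times: list[np.ndarray]
    settings: SimSettings
    params: ModelParams
    signals: tuple[SignalSpec, ...] = ()

    @property
    def n_trials(self) -> int:
        return len(self.spike_times)

    def total_spikes(self, after: float = 0.0) -> int:
        return int(sum(np.count_nonzero(st >= after) for st in self.spike_times))


@dataclass
class RateEstimate:
    """Binned instantaneous firing rate with per-bin standard errors."""

    time: np.ndarray
    rate: np.ndarray
    se: np.ndarray
    bin_width: float
    n_trials: int = 1


def _trial_generators(seed: int, n_trials: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(n_trials)
    return [np.random.Generator(np.random.Philox(s)) for s in seqs]


def simulate(
    params: ModelParams,
    signals: Sequence[SignalSpec] | None,
    settings: SimSettings,
) -> SpikeEnsemble:
    """Integrate the Langevin system and collect spike times for every trial."""
    signals = tuple(signals) if signals else ()
    dt, T, n_trials = settings.dt, settings.T, settings.n_trials
    n_steps = int(round(T / dt))
    gens = _trial_generators(settings.seed, n_trials)

    if settings.initial_state == "stationary":
        theta = np.array([-np.pi + 2 * np.pi * g.random() for g in gens])
        eta = np.array([params.sigma * g.standard_normal() for g in gens])
    else:
        theta = np.full(n_trials, -np.pi)
        eta = np.zeros(n_trials)

    if settings.ou_update == "exact":
        decay = np.exp(-dt / params.tau)
        kick = params.sigma * np.sqrt(max(0.0, 1.0 - decay**2))
    else:
        decay = 1.0 - dt / params.tau
        kick = np.sqrt(2.0 * params.sigma**2 * dt / params.tau)

    trial_ids: list[np.ndarray] = []
    times: list[np.ndarray] = []
    noise = np.empty((min(_CHUNK_STEPS, n_steps), n_trials))
    step = 0
    while step < n_steps:
        chunk = min(_CHUNK_STEPS, n_steps - step)
        for i, g in enumerate(gens):
            noise[:chunk, i] = g.standard_normal(chunk)
        for j in range(chunk):
            t = (step + j) * dt
            s = sum(sig.epsilon * np.cos(sig.omega * t) for sig in signals)
            drive = params.mu + eta + s
            costh = np.cos(theta)
            theta_new = theta + dt * ((1.0 - costh) + (1.0 + costh) * drive)
            crossed = theta_new > np.pi
            if np.any(crossed):
                frac = (np.pi - theta[crossed]) / (theta_new[crossed] - theta[crossed])
                times.append(t + dt * frac)
                trial_ids.append(np.nonzero(crossed)[0])
                theta_new[crossed] -= 2.0 * np.pi
            theta = theta_new
            eta = decay * eta + kick * noise[j]
        step += chunk

    if times:
        all_times = np.concatenate(times)
        all_trials = np.concatenate(trial_ids)
        order = np.argsort(all_trials, kind="stable")  # stable keeps time order
        all_times, all_trials = all_times[order], all_trials[order]
        counts = np.bincount(all_trials, minlength=n_trials)
        splits = np.cumsum(counts)[:-1]
        per_trial = np.split(all_times, splits)
    else:
        per_trial = [np.empty(0) for _ in range(n_trials)]
    return SpikeEnsemble(
        spike_times=[np.asarray(s) for s in per_trial],
        settings=settings,
        params=params,
        signals=signals,
    )


def sample_ou(params: ModelParams, settings: SimSettings) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial OU noise trajectory (t, eta) -- a diagnostic for the noise channel."""
    g = _trial_generators(settings.seed, 1)[0]
    n_steps = int(round(settings.T / settings.dt))
    eta = np.empty(n_steps + 1)
    eta[0] = params.sigma * g.standard_normal()
    if settings.ou_update == "exact":
        decay = np.exp(-settings.dt / params.tau)
        kick = params.sigma * np.sqrt(max(0.0, 1.0 - decay**2))
    else:
        decay = 1.0 - settings.dt / params.tau
        kick = np.sqrt(2.0 * params.sigma**2 * settings.dt / params.tau)
    xi = g.standard_normal(n_steps)
    for j in range(n_steps):
        eta[j + 1] = decay * eta[j] + kick * xi[j]
    return np.arange(n_steps + 1) * settings.dt, eta


def estimate_stationary_rate(e: SpikeEnsemble) -> tuple[float, float]:
    """Spike-count rate after the transient, with across-trial standard error."""
    t0 = e.settings.t_transient
    t_obs = e.settings.T - t0
    if not t_obs > 0:
        raise ValueError("no observation time after the transient")
    per_trial = np.array([np.count_nonzero(st >= t0) for st in e.spike_times], dtype=float)
    rates = per_trial / t_obs
    rate = float(rates.mean())
    se = float(rates.std(ddof=1) / np.sqrt(e.n_trials)) if e.n_trials > 1 else 0.0
    return rate, se


def estimate_rate_psth(e: SpikeEnsemble, bin_width: float) -> RateEstimate:
    """Trial-averaged instantaneous rate on bins covering (t_transient, T]."""
    if bin_width < e.settings.dt:
        raise ValueError("bin_width must be >= dt")
    t0, T = e.settings.t_transient, e.settings.T
    n_bins = int(np.floor((T - t0) / bin_width))
    if n_bins < 1:
        raise ValueError("observation window shorter than one bin")
    edges = t0 + bin_width * np.arange(n_bins + 1)
    all_times = (
        np.concatenate(e.spike_times) if e.total_spikes() else np.empty(0)
    )
    counts, _ = np.histogram(all_times, bins=edges)
    denom = e.n_trials * bin_width
    rate = counts / denom
    se = np.sqrt(np.maximum(counts, 1.0)) / denom  # Poisson-type per-bin error
    centers = edges[:-1] + bin_width / 2.0
    return RateEstimate(time=centers, rate=rate, se=se, bin_width=bin_width, n_trials=e.n_trials)


def estimate_harmonics(
    r: RateEstimate, omega: float, k_list: Sequence[int]
) -> dict[int, tuple[complex, float]]:
    """Complex harmonic amplitudes of the binned rate at multiples of omega.

    Returns ``{k: (h_k, se)}`` with the convention
    ``h_k = (2 - delta_{k,0}) / T_obs * integral r(t) e^{i k omega t} dt`` over
    an integer number of stimulus periods, so that
    ``r(t) ~ h_0 + sum_k |h_k| cos(k omega t - arg h_k)``.  Dividing h_1 by
    the signal amplitude estimates the susceptibility.  The window is
    trimmed down to a whole number of periods; less than one period raises.
    """
    period = 2.0 * np.pi / omega
    t_total = r.time.size * r.bin_width
    n_periods = int(np.floor(t_total / period + 1e-9))
    if n_periods < 1:
        raise ValueError("PSTH window covers less than one stimulus period")
    n_use = int(round(n_periods * period / r.bin_width))
    n_use = min(n_use, r.time.size)
    t, rate, se = r.time[:n_use], r.rate[:n_use], r.se[:n_use]
    t_obs = n_use * r.bin_width
    out: dict[int, tuple[complex, float]] = {}
    for k in k_list:
        prefac = (2.0 - (1.0 if k == 0 else 0.0)) * r.bin_width / t_obs
        weights = prefac * np.exp(1j * k * omega * t)
        val = complex(np.sum(weights * rate))
        var_quad = 0.5 * np.sum((np.abs(weights) * se) ** 2)
        out[k] = (val, float(np.sqrt(var_quad)))
    return out
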