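# thetamcf

Firing rate and stimulus response of the **theta neuron driven by colored
noise**, computed by solving the associated Fokker–Planck equation with the
**matrix-continued-fraction (MCF) method**.

The theta neuron is the phase form of the quadratic integrate-and-fire
neuron, the canonical type-I (integrator) model:

    dθ/dt = (1 − cos θ) + (1 + cos θ)(μ + η(t) + s(t)),

spiking whenever θ crosses π.  The input combines a mean drive μ, an
Ornstein–Uhlenbeck noise η with variance σ² and correlation time τ (all
times in membrane time constants), and optionally one or two periodic
stimuli s(t) = ε cos(ωt).  Because white-noise theory breaks down when the
input correlations are not fast — synaptically filtered inputs, channel
kinetics, oscillatory network noise — the package works at arbitrary τ by
embedding the noise as an extra Markovian dimension and expanding the joint
density P(θ, η) in Fourier × Hermite modes.  The stationary expansion
coefficients obey a tridiagonal matrix recurrence solved by Risken's matrix
continued fraction; periodic stimuli turn into an iterative hierarchy of
banded linear systems whose threshold values give the rate expansion

    r(t) = Σ_{ℓ,k} ε^ℓ |r_{ℓ,k}(ω)| cos(kωt − φ_{ℓ,k}),

i.e. the susceptibility χ(ω) = r_{1,1}, the stimulus-induced mean-rate shift
r_{2,0}, higher harmonics r_{2,2}, r_{3,3}, …, and — for two stimuli — the
mixed terms at ω₁ ± ω₂ that resonate when those combinations match the
firing frequency.  A Langevin (Euler–Maruyama) spike-train simulator with
exact OU updates provides the Monte-Carlo ground truth, and closed-form
limits (deterministic rate √μ/π, quasi-static average, weak-noise
correction, low/high-frequency susceptibility) anchor every regime.

Intended users: computational neuroscientists studying rate coding and
signal transmission under temporally correlated input, and anyone needing a
fast, verifiable alternative to brute-force simulation of a 2-D
Fokker–Planck problem.

## Worked example

```python
import numpy as np
from thetamcf import (ModelParams, SignalSpec, SimSettings, TruncationSpec,
                      estimate_stationary_rate, simulate,
                      stationary_rate_with_check, susceptibility)

p = ModelParams(mu=0.5, sigma=1.0, tau=1.0)   # mean-driven, O(1) colored noise
trunc = TruncationSpec(n_max=150, p_max=150)

r0, r0_check = stationary_rate_with_check(p, trunc)
print(f"r0 = {r0:.6f} (threshold-density check {r0_check:.6f})")

chi = susceptibility(p, omega=2.0, trunc=trunc)
print(f"|chi(2)| = {abs(chi):.4f}, phase = {np.angle(chi):.4f} rad")

ens = simulate(p, None, SimSettings(dt=5e-3, T=50, n_trials=2000, seed=1,
                                    t_transient=10))
print("simulation: %.4f +- %.4f" % estimate_stationary_rate(ens))
```

prints

```
r0 = 0.215048 (threshold-density check 0.215048)
|chi(2)| = 0.2252, phase = 1.6629 rad
simulation: 0.2141 +- 0.0010
```

The two independent rate formulas agree to eight digits (the truncation
check), the colored noise has *lowered* the rate below the deterministic
value √0.5/π ≈ 0.2251 — a type-I-specific effect of slow input correlations
— and the Monte-Carlo estimate agrees within its standard error band.  The
stimulus at ω = 2 is transmitted with 22.5% gain per unit amplitude and a
1.66 rad phase lag.

The same computations are available from the shell:

```bash
thetamcf stationary-rate --mu 0.5 --sigma2 1 --tau 1
thetamcf scan --mu-grid -2:3:51 --tau-grid 0.01:10:41 --log-tau
thetamcf response --mu 1 --tau 0.1 --p-max 151 --order 2 --omega-grid 0.6:1.4:40
thetamcf two-signal --mu 1 --tau 0.05 --p-max 101 --omega1 0.5 --omega2 1.5
thetamcf verify --suite quick
```

Every command writes an RFC-4180 CSV plus a JSON sidecar with the complete
configuration and library versions.  Note that μ = 1 requires an odd
`p_max` (see `docs/methods.md` for the parity pitfall).

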