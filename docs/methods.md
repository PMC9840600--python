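# Methods

## Model

The package treats the theta neuron, the phase normal form of the quadratic
integrate-and-fire (QIF) neuron at a saddle-node-on-invariant-circle
bifurcation.  With all times in units of the membrane time constant the
dynamics is

    dθ/dt = (1 − cos θ) + (1 + cos θ) · (μ + η(t) + s(t)),

a spike being registered when θ passes π (the phase then wraps to −π; no
reset rule is needed).  The input has a constant mean μ (μ < 0: excitable
regime, μ > 0: mean-driven), an Ornstein–Uhlenbeck (OU) noise η with
autocorrelation σ²·exp(−Δt/τ), and optionally one or two cosine stimuli
ε·cos(ωt).  The OU noise is realized by Markovian embedding — an auxiliary
SDE τ dη/dt = −η + √(2τσ²) ξ(t) — so the pair (θ, η) is Markovian and obeys
a two-dimensional Fokker–Planck equation (FPE) with periodic boundary in θ,
natural boundaries in η, and unit normalization.

Two exact parameter reductions are provided.  The *constant-variance*
scaling maps (μ, σ, τ) → (μ/σ, 1, √σ·τ) with rate factor √σ; the
*constant-intensity* scaling fixes D = σ²τ = 1 via (μ/D^{2/3}, ·, D^{1/3}τ)
with rate factor D^{1/3}.  The first makes the noise vanish as τ → 0, the
second has a nontrivial white-noise limit.  All rates are dimensionless
(inverse membrane times); dividing by the membrane time constant in seconds
converts to Hz.

## Spectral representation

Densities are expanded in the product basis of Fourier modes e^{inθ} (they
satisfy the periodic boundary) and Hermite functions φ_p(η) (eigenfunctions
of the OU Fokker–Planck operator; φ₀² is the stationary Gaussian of
variance σ²).  The two properties of the Hermite functions everything rests
on are the eigenrelation L_OU(φ₀φ_p) = −(p/τ)·φ₀φ_p and the ladder relation
η·φ_p = σ(√(p+1)·φ_{p+1} + √p·φ_{p−1}); both are the standard Risken
construction and are unit-tested against small-p closed forms through the
matrices they generate.  The expansion is truncated at n_max Fourier and
p_max Hermite modes (`TruncationSpec`).

### Stationary state: matrix continued fraction

In coefficient space the stationary FPE becomes a tridiagonal three-term
matrix recurrence K_n c_n = c_{n−1} + c_{n+1} between Hermite-coefficient
vectors c_n, with K_n = 2(B⁻¹ − 1) − B⁻¹A/n built from the diagonal OU
relaxation matrix A (entries i·q/τ) and the symmetric tridiagonal drift
matrix B = ((1−μ)·1 − ladder)/2.  The recurrence is closed from above by
transition matrices c_{n+1} = S_n c_n satisfying the backward matrix
continued fraction S_{n−1} = (K_n − S_n)⁻¹, initialized with S_{n_max} = 0.
Starting from the normalization vector c₀ = (1, 0, …) all coefficients
follow, negative n by complex conjugation.

The stationary rate is computed twice, from independent identities: (i) the
probability-current integral, a closed expression in c_{1,0} and c_{1,1},
and (ii) twice the η-integrated density at the threshold phase, an
alternating sum over the whole c_{n,0} column.  Their relative difference
estimates the truncation error; the solver warns beyond 1e−6 (raise with
`strict=True`).  We deliberately warn instead of raising because in the
weak-noise excitable regime (small D = σ²τ, μ < 0) the density approaches a
point mass at the stable fixed point: the threshold Fourier series then
converges at no practical truncation while the rate itself is numerically
zero; the current-based value remains the returned quantity.  This regime —
and, at the opposite end, very long correlation times — is where the
spectral method is known to degrade.

### A parity pitfall at μ = 1

At μ = 1 the drift matrix B = −ladder/2 has a spectrum symmetric around
zero, which contains an exact zero eigenvalue whenever its dimension
p_max + 1 is odd.  The solver detects the resulting ill-conditioning
(condition number above 1e12) and raises with advice to change p_max; all
built-in computations at μ = 1 use odd p_max (101, 151, 201).

### Periodic driving: cyclo-stationary hierarchy

Under a stimulus ε·cos(ωt) the density tends to a cyclo-stationary state,
expanded in powers of ε and harmonics e^{−ikωt}.  Each member P_{ℓ,k} obeys
an inhomogeneous equation (L₀ + ikω)P_{ℓ,k} = ½·L_per(P_{ℓ−1,k−1} +
P_{ℓ−1,k+1}) forced by the previous order, where L_per = ∂_θ(1 + cos θ);
members with |k| > ℓ or k + ℓ odd vanish, and negative k follows by
conjugation.  Rather than generalizing the continued fraction to the
inhomogeneous case, each member is solved as one banded linear system over
all (n, p) (LAPACK `gbsv`, bandwidth p_max + 2): the route is
direct-residual-verifiable, and every solve checks
‖L_k x − rhs‖_∞ < 1e−9·max(1, ‖rhs‖_∞).  For k = 0 the operator is singular
(its null space is the stationary density); the (n, p) = (0, 0) row is
replaced by the normalization constraint c_{0,0} = 0, which every
correction term satisfies exactly.

Rate terms follow by evaluating members at the threshold phase:
r_{ℓ,k} = 2(2 − δ_{k0})·∫dη P_{ℓ,k}(π, η), giving the reconstruction
r(t) = Σ ε^ℓ |r_{ℓ,k}| cos(kωt − φ_{ℓ,k}).  r_{1,1}(ω) is the
susceptibility χ(ω); r_{2,0} the stimulus-induced shift of the mean rate;
r_{2,2}, r_{3,3}, … the higher harmonics, which resonate near the
deterministic angular frequency ω_det = 2π·r_det and its integer fractions.
The cost of each additional order grows roughly linearly: order ℓ adds
⌊ℓ/2⌋ + 1 new members, each one banded solve.

Two simultaneous stimuli use the same machinery with harmonic offsets
k₁ω₁ + k₂ω₂; the package solves the complete second-order set (ℓ₁+ℓ₂ ≤ 2),
including the interaction members at the sum and difference frequencies
whose amplitudes resonate when |ω₁ ± ω₂| ≈ 2π·r_det.  Combinations with
k₁ω₁ + k₂ω₂ ≈ 0 (within 1e−6) for (k₁,k₂) ≠ (0,0) make the operator
singular and are rejected with advice to perturb a frequency; arbitrary-order
two-signal expansions are out of scope.  The normalization integral for the
two-signal members is taken over the full η line, consistent with the
single-signal case.

## Closed-form references

Four limits serve as independent anchors: the deterministic rate
r_det = √μ/π·Θ(μ); the quasi-static (τ → ∞) rate, the Gaussian average of
r_det computed by adaptive quadrature on the half line (relative tolerance
1e−10); the weak-noise phase-response correction
r₀ ≈ r_det − (σ²/2π)(τ²/√μ)/(4μτ² + 1); and the susceptibility limits
|χ(ω→0)| = ∂r₀/∂μ (central difference, default step dμ = 1e−3 — small
enough for the smooth r₀(μ), large enough to stay above solver noise) and
|χ(ω→∞)| = 2r₀/ω² with phase π.  A further oracle used only in the tests is
the white-noise QIF rate at fixed D, evaluated from the mean-first-passage
integral with the inner Gaussian integral done analytically:
T = (1/D)∫₀^∞ dw √(πD/w)·exp(−w³/(12D) − μw/D).

In practice the ω → 0 checks are evaluated at ω = 1e−3 and the ω → ∞ checks
at ω = 50: beyond the resonant region yet inside comfortable numerical
conditioning.

## Langevin simulator

The Euler–Maruyama simulator is the package's ground truth.  The phase is
advanced explicitly with time step dt = 5e−3 by default; the noise channel
uses the exact OU transition η ← η·e^{−dt/τ} + σ√(1 − e^{−2dt/τ})·ξ, which
is exact in distribution for any dt (a plain Euler mode is kept for
comparison).  Spikes are detected by the sign change of θ − π with linear
interpolation of the crossing time, which removes the leading O(dt) bias of
grid-aligned detection — the deterministic period at μ = 1 is reproduced to
five digits at dt = 5e−3.  Trials use independent counter-based random
streams (SeedSequence → Philox), so ensembles are bit-reproducible for a
given seed.  Initial conditions default to stationary draws (η Gaussian, θ
uniform followed by a discarded transient); a reset mode (θ = −π, η = 0)
supports transient studies.

Estimators: the stationary rate is the spike count over observed time with
across-trial standard error; the PSTH divides trial-summed bin counts by
n_trials·bin_width with Poisson per-bin errors; harmonic amplitudes are
Fourier projections of the PSTH over a whole number of stimulus periods
(the window is trimmed down to full periods; less than one period is an
error), and h₁/ε estimates χ(ω).

What the simulator emulates — and does not: it is the same mathematical
model as the FPE, so agreement validates the numerics, not the biological
realism; no refractoriness, adaptation, network interaction, or
non-Gaussian noise is represented, and conclusions about real neurons
inherit all assumptions of the theta-neuron-plus-OU idealization.

## Numerical choices and problem sizes

Default truncation is n_max = p_max = 150, which matches the large
parameter scans; long correlation times (τ ≳ 5) and strongly excitable
points use 200, and the response computations run at 100–200 depending on
the sharpness of the resonances (small τ sharpens them).  Tests and
verification runs size their Monte-Carlo ensembles at 1500–2000 trials of
length 50 (transient 10), which puts 3-standard-error agreement bands at
roughly the percent level — tight enough to detect real defects while
keeping a full run in minutes on one core.  Matrix inversions in the
continued fraction monitor conditioning and raise on singularity (including
the degenerate A = 0, B = 1 configuration, where every K_n vanishes and the
fraction has no finite value).

Known limitations: accuracy degrades for very long correlation times and
for weak noise in the excitable regime (see above); the two-signal module
is second order only; the spike-train power spectrum and non-OU colored
noises are not implemented.
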