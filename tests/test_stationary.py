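"""Stationary matrix-continued-fraction solver: matrices, recursion, rates, densities."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from thetamcf import (
    ModelParams,
    SingularOperatorError,
    TruncationSpec,
    TruncationWarning,
    build_A,
    build_B,
    build_K,
    continued_fraction_S,
    deterministic_rate,
    joint_density,
    marginal_phase_density,
    stationary_coefficients,
    stationary_rate,
    stationary_rate_with_check,
)


def white_noise_qif_rate(mu: float, D: float) -> float:
    """Independent oracle: white-noise QIF rate via the mean-first-passage integral.

    For dx/dt = mu + x^2 + sqrt(2D) xi the passage time from -inf to +inf is
    T = (1/D) int_0^inf dw sqrt(pi D / w) exp(-w^3/(12 D) - mu w / D)
    (the inner Gaussian integral of the standard double-integral formula done
    analytically); the rate is 1/T.
    """
    f = lambda w: math.sqrt(math.pi * D / w) * math.exp(-(w**3) / (12 * D) - mu * w / D)
    T, _ = quad(f, 0, np.inf, limit=400)
    return D / (T * D)


class TestMatrices:
    def test_build_A_examples(self):
        assert np.allclose(build_A(1, 1.0), np.diag([0.0, 1j]))
        assert np.allclose(build_A(2, 2.0), np.diag([0.0, 0.5j, 1j]))

    def test_build_A_is_diagonal(self):
        A = build_A(5, 0.7)
        assert np.count_nonzero(A - np.diag(np.diag(A))) == 0

    def test_build_B_example(self):
        B = build_B(1, -1.0, 1.0)
        assert np.allclose(B, [[1.0, -0.5], [-0.5, 1.0]])

    def test_build_B_zero_noise_is_scaled_identity(self):
        assert np.allclose(build_B(3, 0.2, 0.0), 0.4 * np.eye(4))

    def test_build_B_symmetric(self):
        B = build_B(6, 0.3, 1.7)
        assert np.allclose(B, B.T)

    def test_build_K_trivial(self):
        K = build_K(1, np.zeros((2, 2)), np.eye(2))
        assert np.allclose(K, 0.0)

    def test_build_K_hand_inversion_oracle(self):
        """2x2 case checked against the hand-computed inverse of B."""
        A = build_A(1, 1.0)
        B = build_B(1, -1.0, 1.0)
        Binv = np.array([[4 / 3, 2 / 3], [2 / 3, 4 / 3]])  # inverse of [[1,-.5],[-.5,1]]
        expected = 2 * (Binv - np.eye(2)) - Binv @ np.diag([0.0, 1j])
        assert np.allclose(build_K(1, A, B), expected, atol=1e-14)

    def test_build_K_large_n_limit(self):
        A = build_A(2, 1.0)
        B = build_B(2, 0.0, 1.0)
        Binv = np.linalg.inv(B)
        assert np.allclose(build_K(10**9, A, B), 2 * (Binv - np.eye(3)), atol=1e-6)

    def test_singular_B_rejected(self):
        # at mu=1 the spectrum of B is symmetric around 0; odd dimension => singular
        with pytest.raises(SingularOperatorError):
            build_K(1, build_A(2, 1.0), build_B(2, 1.0, 1.0))


class TestContinuedFraction:
    def test_defining_relation_at_n1(self):
        p = ModelParams(0.5, 1.0, 1.0)
        trunc = TruncationSpec(40, 40)
        S = continued_fraction_S(p, trunc)
        A, B = build_A(40, 1.0), build_B(40, 0.5, 1.0)
        K1 = build_K(1, A, B)
        # S_0 = (K_1 - S_1)^{-1}  <=>  (K_1 - S_1) S_0 = 1
        resid = (K1 - S[1]) @ S[0] - np.eye(41)
        assert np.max(np.abs(resid)) < 1e-10

    def test_self_convergence_in_n_max(self):
        p = ModelParams(0.5, 1.0, 1.0)
        S150 = continued_fraction_S(p, TruncationSpec(150, 150))[0]
        S300 = continued_fraction_S(p, TruncationSpec(300, 150))[0]
        assert np.max(np.abs(S150 - S300)) < 1e-8

    def test_degenerate_configuration_rejected(self):
        # A = 0 (infinite correlation time) and B = identity (mu=-1, sigma=0)
        # make every K_n vanish: the truncated fraction has no finite value.
        p = ModelParams(mu=-1.0, sigma=0.0, tau=math.inf)
        with pytest.raises(SingularOperatorError):
            continued_fraction_S(p, TruncationSpec(10, 10))


class TestStationaryCoefficients:
    def test_normalization_and_conjugation(self, workhorse_params, trunc100):
        c = stationary_coefficients(workhorse_params, trunc100)
        assert c.get(0, 0) == pytest.approx(1.0)
        for n in (1, 5, 40):
            assert np.allclose(c.vector(-n), np.conj(c.vector(n)))

    def test_first_column_from_transition_matrix(self, workhorse_params):
        trunc = TruncationSpec(60, 60)
        S0 = continued_fraction_S(workhorse_params, trunc)[0]
        c = stationary_coefficients(workhorse_params, trunc)
        assert c.get(1, 0) == pytest.approx(S0[0, 0])
        assert c.get(1, 1) == pytest.approx(S0[1, 0])

    def test_three_term_recurrence_residual(self, workhorse_params):
        """Direct substitution into K_n c_n = c_{n-1} + c_{n+1}."""
        trunc = TruncationSpec(80, 80)
        c = stationary_coefficients(workhorse_params, trunc)
        A = build_A(80, workhorse_params.tau)
        B = build_B(80, workhorse_params.mu, workhorse_params.sigma)
        for n in range(1, trunc.n_max):
            K = build_K(n, A, B)
            resid = K @ c.vector(n) - c.vector(n - 1) - c.vector(n + 1)
            assert np.max(np.abs(resid)) < 1e-8

    def test_fourier_coefficients_bounded(self):
        # Fourier coefficients of a probability density never exceed its mass.
        c = stationary_coefficients(ModelParams(-0.5, 0.3, 0.5), TruncationSpec(80, 80))
        assert np.all(np.abs(c.coeffs[:, 0]) <= 1.0 + 1e-9)


class TestStationaryRate:
    def test_short_correlation_time_recovers_deterministic(self):
        r = stationary_rate(ModelParams(1.0, 1.0, 1e-3), TruncationSpec(100, 101))
        assert r == pytest.approx(1 / np.pi, rel=1e-3)

    def test_excitable_weak_effective_noise_rate_vanishes(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TruncationWarning)
            r = stationary_rate(ModelParams(-1.0, 1.0, 1e-3), TruncationSpec(150, 150))
        assert abs(r) < 1e-3

    def test_rate_formulas_agree(self, workhorse_params, trunc100):
        r_current, r_threshold = stationary_rate_with_check(workhorse_params, trunc100)
        assert abs(r_current - r_threshold) < 1e-6 * abs(r_current)

    def test_strict_mode_raises_in_degenerate_regime(self):
        from thetamcf import ConvergenceError

        with pytest.raises(ConvergenceError):
            stationary_rate(
                ModelParams(-1.0, 1.0, 1e-3), TruncationSpec(60, 60), strict=True
            )

    def test_scaling_invariance(self):
        """r(mu, sigma, tau) = sqrt(sigma) * r(mu/sigma, 1, sqrt(sigma) tau)."""
        trunc = TruncationSpec(100, 101)  # odd p_max: mu=1 sits on the singular-B line
        r = stationary_rate(ModelParams(1.0, 4.0, 0.25), trunc)
        r_hat = stationary_rate(ModelParams(0.25, 1.0, 0.5), trunc)
        assert r == pytest.approx(2.0 * r_hat, rel=1e-6)

    def test_colored_noise_can_raise_and_lower_rate(self):
        """Excitable: always raised; mean-driven at tau=1: sign change in (0.1, 1)."""
        trunc = TruncationSpec(100, 100)
        assert stationary_rate(ModelParams(-0.5, 1.0, 1.0), trunc) > 0
        d_low = stationary_rate(ModelParams(0.1, 1.0, 1.0), trunc) - float(
            deterministic_rate(0.1)
        )
        d_high = stationary_rate(ModelParams(1.0, 1.0, 1.0), TruncationSpec(100, 101)) - float(
            deterministic_rate(1.0)
        )
        assert d_low > 0 > d_high

    def test_constant_intensity_below_white_noise_limit(self):
        """At fixed D=1 the colored-noise rate stays below the white-noise rate."""
        for mu in (0.0, 1.0):
            r_wn = white_noise_qif_rate(mu, 1.0)
            for tau in (0.1, 0.3, 1.0):
                sigma = math.sqrt(1.0 / tau)
                pm = 101 if mu == 1.0 else 100
                r = stationary_rate(ModelParams(mu, sigma, tau), TruncationSpec(100, pm))
                assert r < r_wn

    def test_truncation_convergence_monotone(self, workhorse_params):
        r40 = stationary_rate(workhorse_params, TruncationSpec(40, 40))
        r80 = stationary_rate(workhorse_params, TruncationSpec(80, 80))
        r160 = stationary_rate(workhorse_params, TruncationSpec(160, 160))
        assert abs(r80 - r160) < abs(r40 - r80)


class TestDensities:
    @pytest.fixture()
    def excitable_coeffs(self):
        return stationary_coefficients(ModelParams(-1.0, 1.0, 0.5), TruncationSpec(120, 120))

    def test_marginal_normalized_and_nonnegative(self, excitable_coeffs):
        theta = np.linspace(-np.pi, np.pi, 2001)
        dens = marginal_phase_density(excitable_coeffs, theta_grid=theta)
        assert np.trapezoid(dens, theta) == pytest.approx(1.0, abs=1e-8)
        assert dens.min() > -1e-6

    def test_marginal_peaks_at_stable_fixed_point(self, excitable_coeffs):
        """Excitable regime: density maximal near theta* = 2 atan(-sqrt(-mu))."""
        theta = np.linspace(-np.pi, np.pi, 721)
        dens = marginal_phase_density(excitable_coeffs, theta_grid=theta)
        theta_star = 2 * np.arctan(-1.0)  # mu = -1
        assert abs(theta[np.argmax(dens)] - theta_star) < 0.3

    def test_uniform_coefficients_give_uniform_density(self, workhorse_params):
        from thetamcf import CoefficientSet

        trunc = TruncationSpec(10, 5)
        coeffs = np.zeros((21, 6), dtype=complex)
        coeffs[10, 0] = 1.0
        c = CoefficientSet(coeffs, workhorse_params, trunc)
        theta = np.linspace(-np.pi, np.pi, 50)
        assert np.allclose(
            marginal_phase_density(c, theta_grid=theta), 1.0 / (2 * np.pi)
        )

    def test_joint_density_marginals(self, workhorse_params, trunc100):
        c = stationary_coefficients(workhorse_params, trunc100)
        theta = np.linspace(-np.pi, np.pi, 241)
        eta = np.linspace(-6, 6, 301)
        joint = joint_density(c, theta_grid=theta, eta_grid=eta)
        # eta-marginal reproduces the phase density
        marg_theta = np.trapezoid(joint, eta, axis=1)
        assert np.allclose(marg_theta, marginal_phase_density(c, theta_grid=theta), atol=1e-6)
        # theta-marginal reproduces the stationary OU Gaussian
        marg_eta = np.trapezoid(joint, theta, axis=0)
        gauss = np.exp(-(eta**2) / 2.0) / np.sqrt(2 * np.pi)
        assert np.allclose(marg_eta, gauss, atol=1e-6)
        # total mass one, pointwise nonnegative up to ripple
        total = np.trapezoid(np.trapezoid(joint, eta, axis=1), theta)
        assert total == pytest.approx(1.0, abs=1e-6)
        assert joint.min() > -1e-6
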