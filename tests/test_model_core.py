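"""Intrafusal fiber mechanics: equilibria, integration accuracy, rate maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from spindlesim.model_core import (
    DegenerateDenominatorWarning,
    FiberParameters,
    FiberState,
    StretchInput,
    bag1_rate,
    bag2_chain_rate,
    fusimotor_coefficients,
    passive_equilibrium_tension,
    signpow,
    step_fiber,
    tension_derivative,
)
from conftest import random_fiber_params


def linear_fiber(**overrides) -> FiberParameters:
    """Stiff-sensory-region fiber with a_exp=1 (linear spring-dashpot limit)."""
    defaults = dict(
        k_sr=100.0, k_pr=1.0, beta0=20.0, a_exp=1.0, c_damp=1.0,
        r_thresh=0.46, l0_sr=0.04, l0_pr=0.76, ln_sr=0.05, ln_pr=0.85,
        g_gain=100.0, x_frac=0.5, l_secondary=0.04,
    )
    defaults.update(overrides)
    return FiberParameters(**defaults)


class TestSignpow:
    @pytest.mark.parametrize(
        "x, a, expected", [(-4.0, 0.5, -2.0), (0.0, 0.3, 0.0), (2.0, 1.0, 2.0)]
    )
    def test_known_values(self, x, a, expected):
        assert signpow(x, a) == pytest.approx(expected)

    @settings(derandomize=True, deadline=None)
    @given(
        x=st.floats(-1e3, 1e3, allow_nan=False),
        a=st.floats(0.1, 3.0, allow_nan=False),
    )
    def test_odd_and_monotone(self, x, a):
        assert signpow(-x, a) == pytest.approx(-signpow(x, a), abs=1e-12)
        assert signpow(x + 1.0, a) >= signpow(x, a)

    def test_rejects_nonpositive_exponent(self):
        with pytest.raises(ValueError):
            signpow(1.0, 0.0)


class TestFusimotorCoefficients:
    def test_passive_case(self):
        p = linear_fiber(beta0=0.1, beta1=0.2, gamma1=3.0, gamma2=2.0)
        assert fusimotor_coefficients(p, 0.0, 0.0) == (0.1, 0.0)

    def test_linear_in_activations(self):
        p = linear_fiber(beta0=0.1, beta1=0.2, beta2=0.0, gamma1=3.0, gamma2=2.0)
        beta, gamma = fusimotor_coefficients(p, 0.5, 0.0)
        assert beta == pytest.approx(0.2)
        beta, gamma = fusimotor_coefficients(p, 0.0, 1.0)
        assert gamma == pytest.approx(2.0)

    @pytest.mark.parametrize("f_dyn, f_stat", [(-0.1, 0.0), (0.0, 1.5), (2.0, 2.0)])
    def test_rejects_out_of_range_activation(self, f_dyn, f_stat):
        with pytest.raises(ValueError):
            fusimotor_coefficients(linear_fiber(), f_dyn, f_stat)


class TestPassiveEquilibrium:
    def test_hand_computed_example(self):
        # K_SR=2, K_PR=1, L0SR=0.04, L0PR=0.76, L=1:
        # L_PR* = (2*0.96 + 0.76)/3 = 0.89333..., T* = 2*(1-0.89333...-0.04)
        p = linear_fiber(k_sr=2.0, k_pr=1.0)
        assert passive_equilibrium_tension(p, 1.0) == pytest.approx(0.13333333333)

    def test_zero_at_both_rest_lengths(self):
        p = linear_fiber()
        assert passive_equilibrium_tension(p, p.l0_sr + p.l0_pr) == pytest.approx(0.0)

    def test_matches_root_of_force_balance(self, rng):
        # independent oracle: root-find the polar/sensory force balance in T
        for _ in range(20):
            p = random_fiber_params(rng)
            L = rng.uniform(0.9, 1.1)
            gamma = rng.uniform(0.0, 0.05)

            def balance(T):
                l_pr = L - p.l0_sr - T / p.k_sr
                return T - p.k_pr * (l_pr - p.l0_pr) - gamma

            t_root = brentq(balance, -10.0, 10.0, xtol=1e-14)
            assert passive_equilibrium_tension(p, L, gamma) == pytest.approx(
                t_root, abs=1e-10
            )

    def test_gamma_raises_equilibrium_tension(self):
        # polar contraction stretches the sensory region: dT*/dGamma > 0
        p = linear_fiber(k_sr=2.0, k_pr=1.0)
        t0 = passive_equilibrium_tension(p, 1.0, 0.0)
        t1 = passive_equilibrium_tension(p, 1.0, 0.3)
        assert t1 > t0
        slope = (t1 - t0) / 0.3
        assert slope == pytest.approx(p.k_sr / (p.k_sr + p.k_pr))

    def test_homogeneous_in_stiffness_scale(self):
        p = linear_fiber(k_sr=2.0, k_pr=1.0)
        p2 = linear_fiber(k_sr=6.0, k_pr=3.0)
        assert passive_equilibrium_tension(p2, 1.0) == pytest.approx(
            3.0 * passive_equilibrium_tension(p, 1.0)
        )


class TestTensionDerivative:
    def test_vanishes_at_equilibrium(self, rng):
        for _ in range(50):
            p = random_fiber_params(rng)
            L = rng.uniform(0.9, 1.1)
            t_star = passive_equilibrium_tension(p, L)
            tdot = tension_derivative(FiberState(t_star), p, L, 0.0)
            assert abs(tdot) < 1e-8

    def test_sign_drives_toward_equilibrium(self, rng):
        for _ in range(20):
            p = random_fiber_params(rng)
            L = rng.uniform(0.95, 1.08)
            t_star = passive_equilibrium_tension(p, L)
            above = tension_derivative(FiberState(t_star * 1.2), p, L, 0.0)
            below = tension_derivative(FiberState(t_star * 0.8), p, L, 0.0)
            assert above < 0 < below

    def test_degenerate_denominator_warns(self):
        p = linear_fiber(k_sr=2.0, k_pr=1.0)
        # choose L so that L_PR = L - l0_sr - T/K_SR lands exactly on R
        T = 0.1
        L = p.r_thresh + p.l0_sr + T / p.k_sr
        with pytest.warns(DegenerateDenominatorWarning):
            tension_derivative(FiberState(T), p, L, 0.0)


class TestStepFiber:
    def test_linear_limit_matches_exponential_relaxation(self):
        # a=1, stiff SR: two-spring-dashpot relaxation with
        # tau = beta*C*d0 / (K_SR*(1 + K_PR/K_SR)), d0 = L - l0_sr - R - T*/K_SR
        p = linear_fiber()
        L = 1.0
        t_star = passive_equilibrium_tension(p, L)
        d0 = L - p.l0_sr - p.r_thresh - t_star / p.k_sr
        tau = p.beta0 * p.c_damp * d0 / (p.k_sr * (1.0 + p.k_pr / p.k_sr))
        u0 = 0.05 * t_star
        dt = 1e-4
        n = 3000
        state = FiberState(t_star + u0)
        worst = 0.0
        for i in range(n):
            state = step_fiber(state, p, L, 0.0, 0.0, 0.0, dt)
            exact = t_star + u0 * math.exp(-(i + 1) * dt / tau)
            worst = max(worst, abs(state.tension - exact) / exact)
        assert worst < 1e-4

    def test_converges_to_equilibrium_linear_case(self):
        p = linear_fiber()
        L = 1.0
        t_star = passive_equilibrium_tension(p, L)
        state = FiberState(1.5 * t_star)
        for _ in range(2000):
            state = step_fiber(state, p, L, 0.0, 0.0, 0.0, 1e-3)
        assert abs(state.tension - t_star) < 1e-6

    def test_first_order_convergence_in_dt(self):
        # Richardson: halving dt roughly halves the error vs a fine reference,
        # measured mid-transient on a soft, slowly relaxing fiber
        p = linear_fiber(k_sr=2.0, k_pr=1.0, beta0=0.5)
        L, t_end = 1.0, 0.05
        t_star = passive_equilibrium_tension(p, L)

        def final_tension(dt):
            state = FiberState(1.3 * t_star)
            for _ in range(int(round(t_end / dt))):
                state = step_fiber(state, p, L, 0.0, 0.0, 0.0, dt, n_substeps=1)
            return state.tension

        ref = final_tension(1e-3 / 64)
        err_h = abs(final_tension(1e-3) - ref)
        err_h2 = abs(final_tension(5e-4) - ref)
        assert 1.5 < err_h / err_h2 < 2.6

    def test_zero_substeps_is_identity(self):
        p = linear_fiber()
        s0 = FiberState(0.123, time=1.0)
        s1 = step_fiber(s0, p, 1.0, 0.5, 0.0, 0.0, 1e-3, n_substeps=0)
        assert s1.tension == s0.tension

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            step_fiber(FiberState(0.1), linear_fiber(), 1.0, 0.0, 0.0, 0.0, 0.0)


class TestRateContributions:
    def test_bag1_threshold_and_linearity(self):
        p = linear_fiber(g_gain=1.0, k_sr=1.0, ln_sr=0.04, l0_sr=0.04)
        assert bag1_rate(p.k_sr * (p.ln_sr - p.l0_sr), p) == pytest.approx(0.0)
        assert bag1_rate(0.5, p) == pytest.approx(0.5)
        p2 = linear_fiber(g_gain=2.0, k_sr=1.0, ln_sr=0.04, l0_sr=0.04)
        assert bag1_rate(0.5, p2) == pytest.approx(1.0)

    def test_bag2_chain_hand_computed(self):
        # X=0.5, Lsec/L0SR=2, Lsec/L0PR=0.08/0.76, K_SR=1, ln_sr=l0_sr=0.04,
        # ln_pr=0, T=0.2, L=1:
        #   0.5*2*0.2 + 0.5*(0.08/0.76)*(1 - 0.2 - 0.04) = 0.2 + 0.04
        p = linear_fiber(
            g_gain=1.0, k_sr=1.0, x_frac=0.5, l_secondary=0.08,
            l0_sr=0.04, l0_pr=0.76, ln_sr=0.04, ln_pr=1e-12,
        )
        expected = 0.5 * 2.0 * 0.2 + 0.5 * (0.08 / 0.76) * (1.0 - 0.2 - 0.04)
        assert bag2_chain_rate(0.2, 1.0, p) == pytest.approx(expected)

    def test_reductions_at_x_extremes(self):
        p_x1 = linear_fiber(g_gain=1.0, x_frac=1.0)
        ratio = p_x1.l_secondary / p_x1.l0_sr
        assert bag2_chain_rate(0.3, 1.0, p_x1) == pytest.approx(
            ratio * bag1_rate(0.3, p_x1)
        )
        p_x0 = linear_fiber(g_gain=1.0, x_frac=0.0)
        # depends on T only through the polar-length term: slope -Lsec/(L0PR*K_SR)
        d = bag2_chain_rate(0.4, 1.0, p_x0) - bag2_chain_rate(0.2, 1.0, p_x0)
        assert d == pytest.approx(-0.2 * p_x0.l_secondary / (p_x0.l0_pr * p_x0.k_sr))

    def test_rates_affine_in_tension(self, rng):
        p = random_fiber_params(rng)
        t_vals = np.array([0.01, 0.02, 0.03])
        for f in (lambda t: bag1_rate(t, p), lambda t: bag2_chain_rate(t, 1.0, p)):
            r = np.array([f(t) for t in t_vals])
            assert r[2] - r[1] == pytest.approx(r[1] - r[0], abs=1e-9)


class TestInputValidation:
    def test_stretch_input_rejects_bad_sampling(self):
        with pytest.raises(ValueError):
            StretchInput(times=[0.0, 0.1, 0.15], length=[1, 1, 1], velocity=[0, 0, 0])
        with pytest.raises(ValueError):
            StretchInput(times=[0.0, 0.1, 0.2], length=[1, -1, 1], velocity=[0, 0, 0])

    def test_fiber_parameters_invariants(self):
        with pytest.raises(ValueError):
            linear_fiber(k_sr=-1.0)
        with pytest.raises(ValueError):
            linear_fiber(a_exp=1.5)
        with pytest.raises(ValueError):
            linear_fiber(x_frac=1.2)
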