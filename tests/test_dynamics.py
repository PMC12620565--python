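import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rwwfit.connectome import build_laplacian
from rwwfit.constants import BiophysicalConstants
from rwwfit.dynamics import (
    NeuralState,
    drift,
    firing_rate,
    firing_rate_derivative,
    input_currents,
    integrate,
)
from rwwfit.params import GainParameters


class TestFiringRate:
    def test_removable_singularity_limit(self):
        # at a*I = b the transfer takes its L'Hopital limit 1/d
        assert firing_rate(125.0 / 310.0, 310, 125, 0.16) == pytest.approx(1 / 0.16)

    def test_continuity_at_singularity(self):
        a, b, d = 310.0, 125.0, 0.16
        for eps in (1e-8, -1e-8):
            val = firing_rate((b + eps) / a, a, b, d)
            assert abs(val - 1 / d) < 1e-6

    def test_large_positive_input_is_asymptotically_linear(self):
        a, b, d = 310.0, 125.0, 0.16
        I = 2.0  # a*I - b = 495
        assert firing_rate(I, a, b, d) == pytest.approx(a * I - b, rel=1e-10)

    def test_value_matches_high_precision_evaluation(self):
        import sympy

        a, b, d, I = 310, 125, sympy.Rational(16, 100), sympy.Rational(4, 10)
        u = a * I - b
        expected = float((u / (1 - sympy.exp(-d * u))).evalf(30))
        assert firing_rate(0.4, 310, 125, 0.16) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(I=st.floats(-5, 5))
    def test_positive_for_all_finite_inputs(self, I):
        assert firing_rate(I, 310, 125, 0.16) > 0
        assert firing_rate(I, 615, 177, 0.087) > 0

    def test_overflow_safe_for_extreme_currents(self):
        assert np.isfinite(firing_rate(-1e6, 310, 125, 0.16))
        assert np.isfinite(firing_rate(1e6, 310, 125, 0.16))

    def test_derivative_matches_finite_differences(self):
        a, b, d = 310.0, 125.0, 0.16
        for I in (-0.5, 0.2, 125 / 310, 0.6):
            fd = (firing_rate(I + 1e-7, a, b, d) - firing_rate(I - 1e-7, a, b, d)) / 2e-7
            assert firing_rate_derivative(I, a, b, d) == pytest.approx(fd, rel=1e-5)


class TestInputCurrents:
    def test_zero_state_zero_background_gives_zero_currents(self, sc_small_norm):
        consts = BiophysicalConstants(i0=0.0, i_ext=0.0, sigma=0.0)
        gains = GainParameters.defaults("gm")
        lap = build_laplacian(sc_small_norm)
        z = np.zeros(6)
        ie, ii = input_currents(z, z, gains, consts, lap)
        np.testing.assert_array_equal(ie, 0.0)
        np.testing.assert_array_equal(ii, 0.0)

    def test_squashed_currents_strictly_inside_unit_interval(self, rng, sc_small_norm, consts):
        gains = GainParameters.defaults("gm")
        lap = build_laplacian(sc_small_norm)
        E = rng.uniform(0, 1, 6)
        I = rng.uniform(0, 2, 6)
        ie, ii = input_currents(E, I, gains, consts, lap)
        assert np.all(np.abs(ie - consts.i_ext) < 1.0)
        assert np.all(np.abs(ii) < 1.0)

    def test_two_node_hand_arithmetic(self, consts):
        lap = np.array([[0.4, -0.4], [-0.4, 0.4]])
        gains = GainParameters("gm", g=0.5, g_ei=0.15, g_ie=1.0, g_ee=0.21)
        E = np.array([0.3, 0.6])
        I = np.array([0.2, 0.1])
        ie, ii = input_currents(E, I, gains, consts, lap)
        # scalar evaluation of the current equations
        for n in range(2):
            cE = lap[n, 0] * E[0] + lap[n, 1] * E[1]
            x_e = consts.w_e * consts.i0 + 0.21 * E[n] + 0.5 * cE - 1.0 * I[n]
            x_i = consts.w_i * consts.i0 + 0.15 * E[n]
            assert ie[n] == pytest.approx(np.tanh(x_e) + consts.i_ext)
            assert ii[n] == pytest.approx(np.tanh(x_i))

    def test_nonfinite_state_rejected(self, sc_small_norm, consts):
        gains = GainParameters.defaults("gm")
        lap = build_laplacian(sc_small_norm)
        E = np.zeros(6)
        E[2] = np.nan
        with pytest.raises(FloatingPointError, match="node"):
            input_currents(E, np.zeros(6), gains, consts, lap)


class TestDrift:
    def test_saturated_excitation_is_pulled_inward(self, sc_small_norm, consts):
        gains = GainParameters.defaults("gm")
        lap = build_laplacian(sc_small_norm)
        dE, _ = drift(np.ones(6), np.full(6, 0.1), gains, consts, lap)
        np.testing.assert_allclose(dE, -1.0 / consts.tau_e)

    def test_empty_gating_with_positive_rate_grows(self, sc_small_norm, consts):
        gains = GainParameters.defaults("gm")
        lap = build_laplacian(sc_small_norm)
        dE, _ = drift(np.zeros(6), np.zeros(6), gains, consts, lap)
        assert np.all(dE > 0)

    def test_single_node_scalar_evaluation(self, consts):
        lap = np.zeros((2, 2))
        gains = GainParameters("gm", g=0.5, g_ei=0.15, g_ie=1.0, g_ee=0.21)
        E, I = np.array([0.4, 0.0]), np.array([0.25, 0.0])
        dE, dI = drift(E, I, gains, consts, lap)
        x_e = consts.w_e * consts.i0 + 0.21 * 0.4 - 1.0 * 0.25
        x_i = consts.w_i * consts.i0 + 0.15 * 0.4
        r_e = firing_rate(np.tanh(x_e), consts.a_e, consts.b_e, consts.d_e)
        r_i = firing_rate(np.tanh(x_i), consts.a_i, consts.b_i, consts.d_i)
        assert dE[0] == pytest.approx(-0.4 / consts.tau_e + 0.6 * consts.gamma * r_e)
        assert dI[0] == pytest.approx(-0.25 / consts.tau_i + r_i)


class TestIntegrate:
    def _setup(self, sc_small_norm):
        gains = GainParameters.defaults("gm")
        lap = build_laplacian(sc_small_norm)
        init = NeuralState(np.full(6, 0.2), np.full(6, 0.1))
        return gains, lap, init

    def test_noiseless_integration_ignores_seed(self, sc_small_norm, consts_det):
        gains, lap, init = self._setup(sc_small_norm)
        t1 = integrate(init, gains, consts_det, lap, 0.001, 200, seed=1)
        t2 = integrate(init, gains, consts_det, lap, 0.001, 200, seed=2)
        np.testing.assert_array_equal(t1.E, t2.E)

    def test_same_seed_bit_identical(self, sc_small_norm, consts):
        gains, lap, init = self._setup(sc_small_norm)
        t1 = integrate(init, gains, consts, lap, 0.001, 200, seed=42)
        t2 = integrate(init, gains, consts, lap, 0.001, 200, seed=42)
        np.testing.assert_array_equal(t1.E, t2.E)
        np.testing.assert_array_equal(t1.I, t2.I)

    def test_noiseless_state_stays_in_bounds_without_clamping(self, sc_small_norm, consts_det):
        gains, lap, init = self._setup(sc_small_norm)
        traj = integrate(init, gains, consts_det, lap, 0.001, 2000)
        assert traj.clamp_events == 0
        assert traj.E.min() >= 0.0 and traj.E.max() <= 1.0
        assert traj.I.min() >= 0.0

    def test_decoupled_nodes_permute_with_node_order(self, consts_det):
        # with vanishing global coupling, node trajectories are independent
        lap = np.array([[0.7, -0.5, -0.2], [-0.5, 0.5, 0.0], [-0.2, 0.0, 0.2]])
        gains = GainParameters("gm", g=1e-300, g_ei=0.15, g_ie=1.0, g_ee=0.21)
        perm = np.array([2, 0, 1])
        init = NeuralState(np.array([0.1, 0.5, 0.8]), np.array([0.1, 0.2, 0.3]))
        init_p = NeuralState(init.E[perm], init.I[perm])
        t = integrate(init, gains, consts_det, lap, 0.001, 500)
        tp = integrate(init_p, gains, consts_det, lap[np.ix_(perm, perm)], 0.001, 500)
        np.testing.assert_allclose(tp.E, t.E[:, perm], atol=1e-12)

    def test_global_variant_equals_localized_with_equal_vectors(self, sc_small_norm, consts):
        lap = build_laplacian(sc_small_norm)
        init = NeuralState(np.full(6, 0.2), np.full(6, 0.1))
        gm = GainParameters("gm", g=0.5, g_ei=0.15, g_ie=1.0, g_ee=0.21)
        lm = GainParameters("lm", g=0.5, g_ei=np.full(6, 0.15),
                            g_ie=np.full(6, 1.0), g_ee=np.full(6, 0.21))
        t1 = integrate(init, gm, consts, lap, 0.001, 300, seed=5)
        t2 = integrate(init, lm, consts, lap, 0.001, 300, seed=5)
        np.testing.assert_array_equal(t1.E, t2.E)

    def test_fixed_point_is_stationary_under_noiseless_integration(self, consts_det):
        from rwwfit.node_analysis import find_fixed_points

        gains = GainParameters("gm", g=1e-300, g_ei=0.15, g_ie=1.0, g_ee=0.21)
        regime = find_fixed_points(gains, consts_det)
        stable = [fp for fp, s in zip(regime.fixed_points, regime.stable) if s]
        assert stable, "default parameters should have a stable fixed point"
        e_star, i_star = stable[0]
        lap = np.zeros((2, 2))
        init = NeuralState(np.full(2, e_star), np.full(2, i_star))
        traj = integrate(init, gains, consts_det, lap, 0.001, 100)
        assert np.abs(np.diff(traj.E, axis=0)).max() < 1e-8

    def test_invalid_arguments_rejected(self, sc_small_norm, consts):
        gains, lap, init = self._setup(sc_small_norm)
        with pytest.raises(ValueError):
            integrate(init, gains, consts, lap, -0.001, 10)
        with pytest.raises(ValueError):
            integrate(init, gains, consts, lap, 0.001, 0)
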