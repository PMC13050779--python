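"""Model parameterization, dynamics, and constraint projections."""

import numpy as np
import pytest

from birnn.core import (
    TAU_BOUNDS,
    BIRNNState,
    ConfigError,
    InitConfig,
    StabilityError,
    apply_dales_law,
    clamp_time_constants,
    excitatory_input,
    forward,
    init_parameters,
    make_sparsity_mask,
    sigmoid,
    step,
)
from birnn.parcel_pipeline import build_network_projection


@pytest.fixture
def toy_projection():
    return build_network_projection({"p1": "A", "p2": "B"})


@pytest.fixture
def toy_params(toy_projection):
    return init_parameters(2, 2, toy_projection,
                           InitConfig(density=1.0, weight_scale=0.2), seed=3)


class TestInit:
    def test_deterministic_given_seed(self, toy_projection):
        a = init_parameters(5, 2, None, seed=9)
        b = init_parameters(5, 2, None, seed=9)
        for name in ("W_EE", "W_EI", "W_IE", "tau_E", "tau_I", "tau_A"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_invariants_hold_after_init(self):
        p = init_parameters(46, 4, None, seed=0)
        p.validate()  # Dale signs, tau ranges, mask consistency
        assert np.all(p.tau_I > p.tau_E.max() - 30)  # inhibitory init slower

    def test_mask_density_with_diagonal(self):
        p = init_parameters(46, 4, None, InitConfig(density=0.3), seed=1)
        expected = round(0.3 * 46 * 46)
        for m in (p.mask_EE, p.mask_EI, p.mask_IE):
            assert int(m.sum()) == expected
            assert np.all(np.diag(m) == 1.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            init_parameters(4, 2, None, InitConfig(density=0.0))
        with pytest.raises(ConfigError):
            init_parameters(4, 2, None, InitConfig(tau_E_init=(1.0, 20.0)))


class TestSparsityMask:
    def test_full_density_all_ones(self):
        np.testing.assert_array_equal(make_sparsity_mask(5, 1.0, seed=0),
                                      np.ones((5, 5)))

    def test_exact_count(self):
        m = make_sparsity_mask(10, 0.3, seed=4)
        assert int(m.sum()) == 30

    def test_deterministic(self):
        np.testing.assert_array_equal(make_sparsity_mask(12, 0.4, seed=7),
                                      make_sparsity_mask(12, 0.4, seed=7))

    def test_distance_informed_masks_prefer_local(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)),
                         rng.normal(5, 0.1, (10, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        m = make_sparsity_mask(20, 0.3, distances=D, seed=2)
        within = m[:10, :10].sum() + m[10:, 10:].sum()
        across = m[:10, 10:].sum() + m[10:, :10].sum()
        assert within > 3 * across


class TestExcitatoryInput:
    def test_zero_weights_passthrough(self, toy_params, toy_projection):
        p = toy_params.copy()
        p.W_EE[:] = 0; p.W_EI[:] = 0; p.W_IE[:] = 0; p.beta = 0.0
        state = BIRNNState.zeros(2, 2)
        x = np.array([0.3, -0.4])
        np.testing.assert_array_equal(
            excitatory_input(x, state, p, toy_projection), x)

    def test_adaptation_cancels_input(self, toy_params, toy_projection):
        p = toy_params.copy()
        p.W_EE[:] = 0; p.W_EI[:] = 0; p.W_IE[:] = 0; p.beta = 1.0
        x = np.array([0.5, 0.25])
        state = BIRNNState(np.zeros(2), np.zeros(2), x.copy(), np.zeros(2))
        np.testing.assert_allclose(
            excitatory_input(x, state, p, toy_projection), 0.0)

    def test_hand_computed_five_term_sum(self, toy_projection):
        p = init_parameters(2, 2, toy_projection,
                            InitConfig(density=1.0), seed=0)
        p.W_EE = np.array([[0.1, 0.2], [0.0, 0.3]])
        p.W_IE = np.array([[-0.4, 0.0], [-0.1, -0.2]])
        p.W_out_gain = np.array([2.0, 0.5])
        p.beta = 0.5
        state = BIRNNState(np.array([0.6, 0.2]), np.array([0.5, 1.0]),
                           np.array([0.1, 0.3]), np.array([0.2, -0.4]))
        x = np.array([1.0, -1.0])
        # parcel 1: x + g_A*hnet_A + WEE.h_E + WIE.h_I - beta*h_A
        exp0 = 1.0 + 2.0 * 0.2 + (0.1 * 0.6 + 0.2 * 0.2) + (-0.4 * 0.5) - 0.05
        exp1 = -1.0 + 0.5 * (-0.4) + 0.3 * 0.2 + (-0.1 * 0.5 - 0.2 * 1.0) - 0.15
        np.testing.assert_allclose(
            excitatory_input(x, state, p, toy_projection), [exp0, exp1])


class TestStep:
    def test_euler_half_sigmoid(self, toy_projection):
        # I_E forced to 0 => sigma = 0.5; dt/tau_E = 0.1 => h_E goes 0 -> 0.05
        p = init_parameters(2, 2, toy_projection, seed=0)
        p.W_EE[:] = 0; p.W_EI[:] = 0; p.W_IE[:] = 0; p.beta = 0.0
        p.tau_E[:] = 10.0; p.dt = 1.0
        state = BIRNNState.zeros(2, 2)
        new = step(state, np.zeros(2), p, toy_projection)
        np.testing.assert_allclose(new.h_E, 0.05)

    def test_fixed_point_is_stationary(self, toy_projection):
        p = init_parameters(2, 2, toy_projection,
                            InitConfig(density=1.0, weight_scale=0.1), seed=5)
        p.W_net[:] = 0; p.b_net[:] = 0
        x = np.full(2, 0.2)
        state = BIRNNState(np.full(2, 0.5), np.full(2, 0.5), np.full(2, 0.5),
                           np.zeros(2))
        for _ in range(20000):  # relax to the constant-input fixed point
            state = step(state, x, p, toy_projection)
        nxt = step(state, x, p, toy_projection)
        np.testing.assert_allclose(nxt.h_E, state.h_E, atol=1e-10)
        np.testing.assert_allclose(nxt.h_A, state.h_A, atol=1e-10)

    def test_tanh_zero_stays_zero(self, toy_params, toy_projection):
        p = toy_params.copy()
        p.W_net = np.array([[0.7, -0.3], [0.2, 0.5]])
        p.b_net[:] = 0
        state = BIRNNState(np.full(2, 0.5), np.zeros(2), np.zeros(2), np.zeros(2))
        new = step(state, np.zeros(2), p, toy_projection)
        np.testing.assert_array_equal(new.h_net, 0.0)

    def test_stability_guard(self, toy_params, toy_projection):
        p = toy_params.copy()
        p.tau_E = np.full(2, 0.5)  # dt/tau = 2 > 1
        with pytest.raises(StabilityError):
            step(BIRNNState.zeros(2, 2), np.zeros(2), p, toy_projection)


class TestForward:
    def test_single_step_output_length(self, toy_params, toy_projection):
        x = np.random.default_rng(0).normal(size=(2, 2))
        preds = forward(toy_params, x, toy_projection)
        assert preds.shape == (2, 1)

    def test_states_bounded_for_long_rollouts(self, toy_params, toy_projection):
        x = np.random.default_rng(1).normal(0, 2, size=(2, 500))
        _, states = forward(toy_params, x, toy_projection, return_states=True)
        for s in states:
            assert np.all(s.h_E >= 0) and np.all(s.h_E <= 1)
            assert np.all(s.h_I >= 0) and np.all(s.h_I <= 1)
            assert np.all(s.h_A >= 0) and np.all(s.h_A <= 1)
            assert np.all(np.abs(s.h_net) <= 1)

    def test_composition_matches_manual_steps(self, toy_params, toy_projection):
        x = np.random.default_rng(2).normal(size=(2, 4))
        preds = forward(toy_params, x, toy_projection)
        state = BIRNNState.zeros(2, 2)
        for t in range(3):
            state = step(state, x[:, t], toy_params, toy_projection)
            expected = (toy_params.readout_gain * state.h_E
                        + toy_params.readout_offset)
            np.testing.assert_allclose(preds[:, t], expected)

    def test_bitwise_reproducible(self, toy_params, toy_projection):
        x = np.random.default_rng(3).normal(size=(2, 50))
        a = forward(toy_params, x, toy_projection)
        b = forward(toy_params, x, toy_projection)
        np.testing.assert_array_equal(a, b)

    def test_memoryless_network_layer(self, toy_params, toy_projection):
        # W_net = 0, b_net = 0 => h_net(t) = tanh(W_in x_t), closed form
        p = toy_params.copy()
        p.W_net[:] = 0; p.b_net[:] = 0
        x = np.random.default_rng(4).normal(size=(2, 10))
        _, states = forward(p, x, toy_projection, return_states=True)
        for t in range(1, 10):
            np.testing.assert_allclose(
                states[t].h_net, np.tanh(toy_projection.W_in @ x[:, t - 1]))

    def test_adaptation_irrelevant_when_beta_zero(self, toy_params,
                                                  toy_projection):
        x = np.random.default_rng(5).normal(size=(2, 60))
        a = toy_params.copy()
        a.beta = 0.0
        a.tau_A[:] = TAU_BOUNDS["A"][1]
        b = a.copy()
        b.tau_A[:] = TAU_BOUNDS["A"][0]  # different adaptation, same preds
        np.testing.assert_allclose(forward(a, x, toy_projection),
                                   forward(b, x, toy_projection))


class TestConstraintProjections:
    def test_dale_clamps(self, toy_params):
        p = toy_params.copy()
        p.W_EE[0, 1] = -0.5
        p.W_IE[1, 0] = 0.3
        out = apply_dales_law(p)
        assert out.W_EE[0, 1] == 0.0
        assert out.W_IE[1, 0] == 0.0

    def test_identity_on_compliant(self, toy_params):
        out = apply_dales_law(toy_params)
        np.testing.assert_array_equal(out.W_EE, toy_params.W_EE)
        np.testing.assert_array_equal(out.W_IE, toy_params.W_IE)

    def test_idempotent(self, toy_params):
        p = toy_params.copy()
        p.W_EE[0, 1] = -2.0
        once = apply_dales_law(p)
        twice = apply_dales_law(once)
        np.testing.assert_array_equal(once.W_EE, twice.W_EE)

    @pytest.mark.parametrize(
        "tau,expected", [(2.0, 5.0), (100.0, 30.0), (17.0, 17.0)])
    def test_tau_clamped_into_range(self, toy_params, tau, expected):
        p = toy_params.copy()
        p.tau_E[:] = tau
        assert clamp_time_constants(p).tau_E[0] == expected

    def test_interior_tau_untouched(self, toy_params):
        p = toy_params.copy()
        p.tau_I[:] = 50.0
        assert clamp_time_constants(p).tau_I[0] == 50.0

    def test_inverted_bounds_rejected(self, toy_params):
        with pytest.raises(ConfigError):
            clamp_time_constants(toy_params, {"E": (30.0, 5.0),
                                              "I": (10.0, 100.0),
                                              "A": (50.0, 500.0)})


def test_sigmoid_stable_at_extremes():
    x = np.array([-1000.0, 0.0, 1000.0])
    np.testing.assert_allclose(sigmoid(x), [0.0, 0.5, 1.0])
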