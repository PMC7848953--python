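"""Unit tests for the TD/MLP machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motivnet.nets import (
    Layer,
    MLPParams,
    PolicySpec,
    TrainSchedule,
    anneal,
    forward,
    init_mlp,
    load_params,
    save_params,
    select_action,
    selected_gradient,
    td_error,
    update_selected,
)


class TestInit:
    def test_same_seed_identical(self):
        a = init_mlp([4, 8, 3], "sigmoid", "xavier", np.random.default_rng(5))
        b = init_mlp([4, 8, 3], "sigmoid", "xavier", np.random.default_rng(5))
        for la, lb in zip(a.layers, b.layers):
            assert np.array_equal(la.W, lb.W) and np.array_equal(la.b, lb.b)

    def test_uniform_bounds(self):
        p = init_mlp(
            [40, 40], "linear", ("uniform", -1e-5, 1e-5), np.random.default_rng(0)
        )
        assert np.all(np.abs(p.layers[0].W) <= 1e-5)

    def test_xavier_variance(self):
        # sample variance of a 36->100 layer within 20% of 2/(fan_in+fan_out)
        rng = np.random.default_rng(1)
        target = 2.0 / (36 + 100)
        variances = [
            init_mlp([36, 100], "sigmoid", "xavier", rng).layers[0].W.var()
            for _ in range(10)
        ]
        assert abs(np.mean(variances) - target) < 0.2 * target

    def test_non_chaining_sizes_error(self):
        layers = [
            Layer(np.zeros((5, 3)), np.zeros(5), "sigmoid"),
            Layer(np.zeros((2, 4)), np.zeros(2), "linear"),
        ]
        with pytest.raises(ValueError, match="chain"):
            MLPParams(layers)


class TestForward:
    def test_zero_weights_sigmoid_half(self):
        p = init_mlp([3, 4, 2], ["sigmoid", "sigmoid"], ("uniform", 0, 0),
                     np.random.default_rng(0))
        cache, out = forward(p, np.ones(3))
        assert np.allclose(cache["activations"][1], 0.5)
        assert np.allclose(out, 0.5)

    def test_leaky_relu_negative_slope(self):
        p = MLPParams([Layer(np.eye(1), np.zeros(1), "leaky_relu", alpha=0.2)])
        _, out = forward(p, np.array([-1.0]))
        assert out[0] == pytest.approx(-0.2)

    def test_hand_computed_toy_net(self):
        W1 = np.array([[0.1, -0.2], [0.3, 0.4]])
        b1 = np.array([0.05, -0.1])
        W2 = np.array([[1.0, -1.5]])
        b2 = np.array([0.2])
        p = MLPParams([Layer(W1, b1, "sigmoid"), Layer(W2, b2, "linear")])
        x = np.array([0.7, -0.3])
        h = 1 / (1 + np.exp(-(W1 @ x + b1)))
        expected = W2 @ h + b2
        _, out = forward(p, x)
        assert np.allclose(out, expected, atol=1e-12)

    def test_dimension_mismatch(self):
        p = init_mlp([3, 2], "linear", "xavier", np.random.default_rng(0))
        with pytest.raises(ValueError, match="shape"):
            forward(p, np.ones(4))


class TestTDError:
    @pytest.mark.parametrize(
        "r, gamma, q_next, q_sel, expected",
        [
            (1.0, 0.9, 2.0, 1.0 + 0.9 * 2.0, 0.0),  # Bellman-consistent
            (5.0, 0.9, 0.0, 5.0, 0.0),  # terminal bootstrap is zero
            (1.0, 0.9, 2.0, 1.0, 1.8),
        ],
    )
    def test_values(self, r, gamma, q_next, q_sel, expected):
        assert td_error(r, gamma, q_next, q_sel) == pytest.approx(expected)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            td_error(1.0, 0.0, 1.0, 1.0)


class TestUpdateSelected:
    def test_zero_delta_noop(self):
        p = init_mlp([3, 4, 2], "sigmoid", "xavier", np.random.default_rng(0))
        before = [l.W.copy() for l in p.layers]
        cache, _ = forward(p, np.ones(3))
        update_selected(p, cache, 0, 0.0, 0.1)
        for W, l in zip(before, p.layers):
            assert np.array_equal(W, l.W)

    def test_non_selected_output_rows_unchanged(self):
        p = init_mlp([3, 4, 5], ["sigmoid", "linear"], "xavier",
                     np.random.default_rng(2))
        cache, _ = forward(p, np.array([0.3, -0.1, 0.8]))
        top_before = p.layers[-1].W.copy()
        update_selected(p, cache, 2, 0.7, 0.05)
        others = [i for i in range(5) if i != 2]
        assert np.array_equal(top_before[others], p.layers[-1].W[others])
        assert not np.array_equal(top_before[2], p.layers[-1].W[2])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        p = init_mlp([3, 4, 5], ["sigmoid", "linear"], "xavier", rng)
        x = rng.normal(size=3)
        sel = 4
        cache, _ = forward(p, x)
        grads = selected_gradient(p, cache, sel)
        eps = 1e-6
        for li, layer in enumerate(p.layers):
            for arr, g in [(layer.W, grads[li][0]), (layer.b, grads[li][1])]:
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    old = arr[idx]
                    arr[idx] = old + eps
                    _, up = forward(p, x)
                    arr[idx] = old - eps
                    _, dn = forward(p, x)
                    arr[idx] = old
                    fd = (up[sel] - dn[sel]) / (2 * eps)
                    assert abs(fd - g[idx]) < 1e-6

    def test_update_shrinks_td_error_on_frozen_transition(self):
        rng = np.random.default_rng(4)
        p = init_mlp([4, 6, 3], ["sigmoid", "linear"], "xavier", rng)
        x, x2 = rng.normal(size=4), rng.normal(size=4)
        r, gamma, a = 1.0, 0.9, 1
        for _ in range(20):
            cache, q = forward(p, x)
            _, q2 = forward(p, x2)
            delta = td_error(r, gamma, float(q2.max()), float(q[a]))
            update_selected(p, cache, a, delta, 0.01)
        cache, q = forward(p, x)
        _, q2 = forward(p, x2)
        final = abs(td_error(r, gamma, float(q2.max()), float(q[a])))
        assert final < abs(delta)

    def test_index_out_of_range(self):
        p = init_mlp([3, 2], "linear", "xavier", np.random.default_rng(0))
        cache, _ = forward(p, np.ones(3))
        with pytest.raises(IndexError):
            update_selected(p, cache, 5, 1.0, 0.1)


class TestSelectAction:
    def test_greedy_when_epsilon_zero(self):
        q = np.array([0.1, 0.9, 0.3])
        pol = PolicySpec("epsilon_greedy", epsilon=0.0)
        rng = np.random.default_rng(0)
        assert all(select_action(q, pol, rng=rng) == 1 for _ in range(20))

    def test_epsilon_one_uniform_over_available(self):
        # chi-square sanity at n = 1e4 over 3 available of 4 actions
        q = np.array([5.0, 1.0, 1.0, 1.0])
        mask = np.array([True, False, True, True])
        pol = PolicySpec("epsilon_greedy", epsilon=1.0)
        rng = np.random.default_rng(1)
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            counts[select_action(q, pol, mask, rng)] += 1
        assert counts[1] == 0
        observed = counts[[0, 2, 3]]
        chi2 = np.sum((observed - n / 3) ** 2 / (n / 3))
        assert chi2 < 13.8  # chi2_{2, 0.001}

    def test_softmax_limit_is_greedy(self):
        q = np.array([0.0, 1.0, 0.5])
        pol = PolicySpec("softmax", beta=1e3)
        rng = np.random.default_rng(2)
        picks = [select_action(q, pol, rng=rng) for _ in range(2000)]
        assert np.mean(np.array(picks) == 1) > 0.999

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="available"):
            select_action(np.ones(3), PolicySpec("deterministic"),
                          np.zeros(3, dtype=bool), np.random.default_rng(0))

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.data(),
        n=st.integers(min_value=2, max_value=8),
        kind=st.sampled_from(["epsilon_greedy", "softmax", "deterministic"]),
    )
    def test_masked_actions_never_chosen(self, data, n, kind):
        mask = np.array(
            data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        )
        if not mask.any():
            mask[data.draw(st.integers(0, n - 1))] = True
        q = np.array(data.draw(
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)
        ))
        pol = {
            "epsilon_greedy": PolicySpec("epsilon_greedy", epsilon=0.5),
            "softmax": PolicySpec("softmax", beta=1.0),
            "deterministic": PolicySpec("deterministic"),
        }[kind]
        choice = select_action(q, pol, mask, np.random.default_rng(0))
        assert mask[choice]


class TestAnneal:
    def test_endpoints_and_midpoint(self):
        assert anneal(3e-3, 3e-5, 0, 100) == pytest.approx(3e-3)
        assert anneal(3e-3, 3e-5, 100, 100) == pytest.approx(3e-5)
        assert anneal(3e-3, 3e-5, 50, 100) == pytest.approx(3e-4)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TrainSchedule(1e-4, 1e-2, 100, 0.9)  # lr_end > lr_start
        with pytest.raises(ValueError):
            TrainSchedule(1e-2, 1e-4, 100, 1.5)  # gamma out of range


class TestChainMDPConvergence:
    def test_tabular_equivalent_net_learns_chain(self):
        # 3-state chain: s0 -> s1 -> s2(terminal), rewards 0, 0, 1 on arrival
        # single action; analytic Q(s0)=gamma^2, Q(s1)=gamma, Q(s2 entry)=1
        gamma = 0.9
        p = init_mlp([3, 1], "linear", ("uniform", 0, 0), np.random.default_rng(0))
        states = np.eye(3)
        for _ in range(3000):
            for s in range(3):
                cache, q = forward(p, states[s])
                if s == 2:
                    target = 1.0
                else:
                    _, qn = forward(p, states[s + 1])
                    target = 0.0 + gamma * qn[0]
                update_selected(p, cache, 0, target - q[0], 0.05)
        got = [forward(p, states[s])[1][0] for s in range(3)]
        assert np.allclose(got, [gamma**2, gamma, 1.0], atol=1e-2)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        p = init_mlp([4, 6, 2], ["leaky_relu", "linear"], "xavier",
                     np.random.default_rng(0), alpha=0.2)
        p.input_spec = {"dim": 4, "center": [0.1, 0.2, 0.3, 0.4]}
        path = tmp_path / "net.npz"
        save_params(p, path)
        q = load_params(path)
        for la, lb in zip(p.layers, q.layers):
            assert np.array_equal(la.W, lb.W)
            assert np.array_equal(la.b, lb.b)
            assert la.activation == lb.activation and la.alpha == lb.alpha
        assert q.input_spec["dim"] == 4
        x = np.ones(4)
        assert np.array_equal(forward(p, x)[1], forward(q, x)[1])
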