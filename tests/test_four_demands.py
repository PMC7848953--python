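"""Four Demands environment, analytics and strategy classification."""

from fractions import Fraction

import numpy as np
import pytest

from motivnet.four_demands import (
    ACTIONS,
    FDConfig,
    FDState,
    STRATEGIES,
    calibrate_input_norm,
    canonical_trajectory,
    classify_strategy,
    consumption_intervals,
    encode_fd,
    fd_step,
    make_addiction_config,
    replay_canonical,
    replay_rooms,
    room_of,
    steady_state_rate,
    strategy_rate,
    theta_sweep,
)


class TestRoomOf:
    @pytest.mark.parametrize(
        "pos, room", [((0, 0), 0), ((0, 5), 1), ((5, 0), 2), ((5, 5), 3), ((2, 3), 1)]
    )
    def test_quadrants(self, pos, room):
        assert room_of(pos) == room

    def test_out_of_grid(self):
        with pytest.raises(ValueError):
            room_of((6, 0))


class TestFdStep:
    def test_staying_gives_alternating_rewards(self):
        cfg = FDConfig(5.0)
        state = FDState((0, 0), np.zeros(4))
        rewards = []
        for _ in range(6):
            state, r = fd_step(cfg, state, "stay")
            rewards.append(r)
        assert rewards == [0, 1, 0, 1, 0, 1]

    def test_migration_per_room_reward_triple(self):
        # steady state: entering a room left 9 steps ago pays 9, then 0, then 1
        pairs = replay_canonical("migration", 100)
        by_room = {}
        for room, reward in pairs[-12:]:
            by_room.setdefault(room, []).append(reward)
        for rewards in by_room.values():
            assert rewards == [9, 0, 1]

    def test_outer_wall_blocks_but_dynamics_advance(self):
        cfg = FDConfig(5.0)
        state = FDState((0, 0), np.array([0.0, 1, 1, 1]))
        nxt, r = fd_step(cfg, state, "up")
        assert nxt.position == (0, 0)
        assert r == 0.0  # room 0 component was 0
        assert np.array_equal(nxt.mu, [1, 2, 2, 2])

    def test_interior_wall_blocks_off_doorway(self):
        cfg = FDConfig(5.0)
        # (2,2) -> right crosses the vertical wall away from a doorway row
        state = FDState((2, 2), np.zeros(4))
        nxt, _ = fd_step(cfg, state, "right")
        assert nxt.position == (2, 2)
        # (1,2) -> right passes through the doorway
        state = FDState((1, 2), np.zeros(4))
        nxt, _ = fd_step(cfg, state, "right")
        assert nxt.position == (1, 3)

    def test_motivation_respects_caps_under_random_rollout(self):
        cfg = FDConfig(np.array([1.0, 2.5, 7.0, 100.0]))
        rng = np.random.default_rng(0)
        state = FDState((3, 3), np.zeros(4))
        for _ in range(2000):
            state, _ = fd_step(cfg, state, ACTIONS[rng.integers(5)])
            assert np.all(state.mu >= 0) and np.all(state.mu <= cfg.theta)

    def test_reward_zero_right_after_consumption_in_same_room(self):
        cfg = FDConfig(50.0)
        state = FDState((1, 1), np.full(4, 10.0))
        state, r1 = fd_step(cfg, state, "stay")
        assert r1 == 10.0
        _, r2 = fd_step(cfg, state, "stay")
        assert r2 == 0.0


class TestEncoding:
    def _calibrated(self, theta=4.0):
        cfg = FDConfig(theta)
        return calibrate_input_norm(cfg, np.random.default_rng(0))

    def test_lengths(self):
        cfg = self._calibrated()
        x = encode_fd(FDState((2, 3), np.zeros(4)), cfg)
        assert x.shape == (40,)
        cfg2 = FDConfig(4.0, theta_as_input=True, theta_input_value=4.0)
        calibrate_input_norm(cfg2, np.random.default_rng(0))
        assert encode_fd(FDState((2, 3), np.zeros(4)), cfg2).shape == (41,)

    def test_position_block_is_shifted_one_hot(self):
        cfg = self._calibrated()
        x = encode_fd(FDState((1, 4), np.zeros(4)), cfg)
        pos = x[:36]
        # exactly one entry is the "hot" value, the rest share the baseline
        hot = np.flatnonzero(pos > pos.min() + 1e-9)
        assert hot.tolist() == [1 * 6 + 4]

    def test_calibrated_variances(self):
        # replaying the calibration distribution: position channels have unit
        # variance each (total 36), motivation channels variance 9 each
        cfg = self._calibrated()
        rng = np.random.default_rng(1)
        state = FDState((0, 0), np.zeros(4))
        xs = []
        for _ in range(10_000):
            state, _ = fd_step(cfg, state, ACTIONS[rng.integers(5)])
            xs.append(encode_fd(state, cfg))
        xs = np.asarray(xs)
        pos_var = xs[:, :36].var(axis=0).sum()
        mu_var = xs[:, 36:].var(axis=0).sum()
        assert pos_var == pytest.approx(36.0, rel=0.10)
        assert mu_var == pytest.approx(36.0, rel=0.10)

    def test_blind_control_zeroes_motivation_channels(self):
        cfg = FDConfig(4.0, motivation_blind=True)
        calibrate_input_norm(cfg, np.random.default_rng(0))
        x = encode_fd(FDState((0, 0), np.array([1.0, 2, 3, 4])), cfg)
        assert np.all(x[36:] == 0.0)


class TestStrategyRates:
    @pytest.mark.parametrize(
        "name, theta, expected",
        [
            ("one_room_binge", 7, Fraction(1, 2)),
            ("two_room_binge", 1, Fraction(1)),
            ("two_room_binge", 50, Fraction(1)),
            ("migration", 9, Fraction(10, 3)),
            ("migration", 100, Fraction(10, 3)),
            ("migration", 1, Fraction(2, 3)),
            ("delayed_migration", 15, Fraction(47, 14)),
            ("delayed_two_room_binge", 2, Fraction(4, 3)),
        ],
    )
    def test_closed_forms(self, name, theta, expected):
        assert strategy_rate(name, theta) == expected

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            strategy_rate("binge_watching", 3)

    @pytest.mark.parametrize("theta", [1, 2, 3, 9, 15, 100])
    @pytest.mark.parametrize("name", STRATEGIES)
    def test_simulation_equals_formula_exactly(self, name, theta):
        # replaying the canonical trajectory through the environment for a
        # steady-state period reproduces the closed form in exact rationals
        assert steady_state_rate(name, theta) == strategy_rate(name, theta)

    def test_orderings(self):
        assert (
            strategy_rate("migration", 100)
            > strategy_rate("two_room_binge", 100)
            > strategy_rate("one_room_binge", 100)
        )
        assert strategy_rate("migration", 1) < strategy_rate("two_room_binge", 1)


class TestClassify:
    def test_alternating_rooms_is_two_room_binge(self):
        label = classify_strategy([0, 1] * 20, 1)
        assert label.name == "two_room_binge"
        assert label.empirical_rate == pytest.approx(1.0)

    def test_migration_template(self):
        start, actions = canonical_trajectory("migration", 4)
        cfg = FDConfig(100.0)
        state = FDState(start, np.zeros(4))
        rooms = []
        for a in actions:
            state, _ = fd_step(cfg, state, a)
            rooms.append(room_of(state.position))
        assert classify_strategy(rooms, 100).name == "migration"

    def test_random_rooms_are_other(self):
        rng = np.random.default_rng(3)
        assert classify_strategy(list(rng.integers(0, 4, 80)), 5).name == "other"

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            classify_strategy([0, 1] * 5, 1)


class TestAddiction:
    def test_caps_vector(self):
        cfg = make_addiction_config(0.9)
        assert np.array_equal(cfg.theta, [1, 1, 1, 10])

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            make_addiction_config(1.0)

    def test_consumption_intervals_on_synthetic_pattern(self):
        # visiting room 3 every 4th step: intervals of 4
        rooms = [0, 1, 0, 3] * 10
        iv = consumption_intervals(rooms, [1, 1, 1, 10])
        assert np.all(iv == 4)


class TestThetaAsInput:
    def test_minibatch_training_switches_caps(self):
        from motivnet.four_demands import default_fd_schedule, train_fd_agent

        cfg = FDConfig(1.0, theta_as_input=True)
        params, log = train_fd_agent(
            cfg, default_fd_schedule(3000), np.random.default_rng(0)
        )
        assert params.n_inputs == 41
        # after training the cap was redrawn from 1..10 per 10-step minibatch
        assert 1.0 <= cfg.theta[0] <= 10.0
        assert len(log["rooms"]) == 500

    def test_extrapolation_input_encodes_novel_cap(self):
        cfg = FDConfig(15.0, theta_as_input=True, theta_input_value=15.0)
        calibrate_input_norm(cfg, np.random.default_rng(0))
        x = encode_fd(FDState((0, 0), np.zeros(4)), cfg)
        assert x.shape == (41,)
        assert x[-1] > 0  # 15 sits above the 1..10 training range


class TestThetaSweep:
    def test_geometric_grid(self):
        grid = theta_sweep()
        assert len(grid) == 41
        assert grid[0] == pytest.approx(1.0) and grid[-1] == pytest.approx(100.0)
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0])


class TestReplayRooms:
    def test_exact_integer_rewards(self):
        rewards = replay_rooms([0, 0, 0, 0], 5)
        assert rewards == [0, 1, 0, 1]
        assert all(isinstance(r, int) for r in rewards)
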