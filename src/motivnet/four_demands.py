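"""The Four Demands grid world and its motivated Q-learning agent.

A 6×6 grid is split into four 3×3 rooms, each dispensing one resource (think
water, food, sleep, play).  The agent carries a 4-component motivation vector
μ: occupying room *n* pays the subjective reward r~ = μ_n, after which μ_n
resets to zero; every component that paid nothing grows by 1 per step until it
saturates at the cap θ.  The cap is the single knob that reshapes the optimal
policy, from two-room binging (small θ) through delayed binging to migration
around all four rooms (large θ).

The canonical periodic strategies have closed-form subjective-reward rates
(``strategy_rate``), which the environment replay reproduces exactly in
rational arithmetic — that equivalence is the main correctness anchor of the
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .nets import (
    MLPParams,
    PolicySpec,
    TrainSchedule,
    forward,
    init_mlp,
    select_action,
    td_error,
    update_selected,
)

__all__ = [
    "GRID",
    "ACTIONS",
    "FDConfig",
    "FDState",
    "StrategyLabel",
    "STRATEGIES",
    "room_of",
    "fd_step",
    "replay_rooms",
    "encode_fd",
    "calibrate_input_norm",
    "train_fd_agent",
    "greedy_rollout",
    "strategy_rate",
    "classify_strategy",
    "canonical_trajectory",
    "make_addiction_config",
    "consumption_intervals",
    "theta_sweep",
]

GRID = 6  # 6×6 cells, four 3×3 rooms
N_ROOMS = 4
ACTIONS = ("up", "down", "left", "right", "stay")
_DELTAS = {"up": (-1, 0), "down": (1, 0), "left": (0, -1), "right": (0, 1), "stay": (0, 0)}

STRATEGIES = (
    "one_room_binge",
    "two_room_binge",
    "delayed_two_room_binge",
    "migration",
    "delayed_migration",
)


@dataclass
class FDConfig:
    """Environment and encoder configuration.

    theta : per-room saturation caps (broadcast from a scalar).
    theta_as_input : append the cap as a 41st input channel (single-network
        variant trained across θ = 1..10 in 10-iteration minibatches).
    motivation_blind : zero the motivation input channels while the true μ
        still drives rewards (the non-motivated control).
    mu_center / mu_scale : motivation-channel normalization constants,
        estimated from a random-walk rollout by ``calibrate_input_norm``.
    """

    theta: np.ndarray
    gamma: float = 0.9
    theta_as_input: bool = False
    theta_input_value: float | None = None
    motivation_blind: bool = False
    mu_center: np.ndarray | None = None
    mu_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.broadcast_to(np.asarray(self.theta, dtype=float), (N_ROOMS,)).copy()
        if np.any(self.theta < 1):
            raise ValueError("every saturation cap must be >= 1")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def n_inputs(self) -> int:
        return GRID * GRID + N_ROOMS + (1 if self.theta_as_input else 0)


@dataclass
class FDState:
    position: tuple  # (row, col), 0-based
    mu: np.ndarray  # (4,) drive levels, 0 <= mu <= theta


@dataclass
class StrategyLabel:
    name: str  # one of STRATEGIES or "other"
    empirical_rate: float


def room_of(position) -> int:
    """Row-major quadrant index: NW=0, NE=1, SW=2, SE=3."""
    r, c = position
    if not (0 <= r < GRID and 0 <= c < GRID):
        raise ValueError(f"position {position} outside the {GRID}x{GRID} grid")
    return 2 * (r // 3) + (c // 3)


def _consume_and_grow(mu, room, theta):
    """Shared motivation update: read reward, reset the consumed component,
    grow every component that paid nothing (capped at theta).

    Works elementwise on plain Python numbers, so integer caps give exact
    integer rewards (used by the rational-arithmetic replay).
    """
    reward = mu[room]
    new_mu = [m + 1 if m + 1 < th else th for m, th in zip(mu, theta)]
    if reward > 0:
        new_mu[room] = 0
    return reward, new_mu


_DOORWAYS = (1, 4)  # rows (cols) where the vertical (horizontal) walls open


def _move_allowed(r: int, c: int, nr: int, nc: int) -> bool:
    """Interior walls separate the rooms; each adjacent pair connects through
    a single doorway at the middle of its shared boundary."""
    if not (0 <= nr < GRID and 0 <= nc < GRID):
        return False
    if c != nc and {c, nc} == {2, 3}:  # crossing the vertical wall
        return r in _DOORWAYS
    if r != nr and {r, nr} == {2, 3}:  # crossing the horizontal wall
        return c in _DOORWAYS
    return True


def fd_step(config: FDConfig, state: FDState, action: str):
    """Apply one action; return ``(next_state, subjective_reward)``.

    Movement into the outer boundary or an interior wall leaves the position
    unchanged but the motivation dynamics still advance.  The reward is the
    motivation toward the room occupied *after* the move.
    """
    dr, dc = _DELTAS[action]
    r, c = state.position
    nr, nc = r + dr, c + dc
    if not _move_allowed(r, c, nr, nc):
        nr, nc = r, c
    room = room_of((nr, nc))
    reward, new_mu = _consume_and_grow(list(state.mu), room, config.theta)
    return FDState((nr, nc), np.asarray(new_mu, dtype=float)), float(reward)


def replay_rooms(rooms, theta, mu0=None):
    """Replay a room-occupancy sequence through the motivation dynamics.

    Returns the per-step subjective rewards.  With integer caps and integer
    initial motivation the rewards are exact integers, so period means can be
    formed as :class:`fractions.Fraction` without rounding.
    """
    if np.isscalar(theta):
        theta = [theta] * N_ROOMS
    theta = list(theta)
    mu = list(mu0) if mu0 is not None else [0] * N_ROOMS
    rewards = []
    for room in rooms:
        reward, mu = _consume_and_grow(mu, room, theta)
        rewards.append(reward)
    return rewards


# ---------------------------------------------------------------------------
# input encoding

# Per-channel target variances 1 (position) and 9 (motivation): with 36
# position channels against 4 motivation channels this balances the two
# blocks' total contributions (36 vs 36).
_N_CELLS = GRID * GRID
_POS_SCALE = float(_N_CELLS / np.sqrt(_N_CELLS - 1.0))  # centered one-hot -> var 1/channel
_MU_STD_TARGET = 3.0  # sqrt(9) per motivation channel
_THETA_CENTER, _THETA_SCALE = 5.5, float(np.sqrt(99.0 / 12.0) / 3.0)  # U{1..10} -> var 9


def calibrate_input_norm(
    config: FDConfig, rng: np.random.Generator, n_steps: int = 10_000
) -> FDConfig:
    """Estimate motivation-channel normalization from a random-walk rollout.

    Each motivation channel is centered by its rollout mean and scaled to
    variance 9, against variance 1 per position channel; the 9:1 per-channel
    ratio offsets the 4:36 channel count so both blocks contribute equally.
    For the θ-as-input variant the cap is resampled from 1..10 every 10
    steps, matching the minibatch schedule the network is trained under.
    """
    theta = config.theta.copy()
    state = FDState((0, 0), np.zeros(N_ROOMS))
    samples = np.empty((n_steps, N_ROOMS))
    cfg = FDConfig(theta, config.gamma)
    for t in range(n_steps):
        if config.theta_as_input and t % 10 == 0:
            cfg.theta[:] = float(rng.integers(1, 11))
            state.mu = np.minimum(state.mu, cfg.theta)
        action = ACTIONS[rng.integers(len(ACTIONS))]
        state, _ = fd_step(cfg, state, action)
        samples[t] = state.mu
    center = samples.mean(axis=0)
    std = samples.std(axis=0)
    std[std < 1e-6] = 1.0
    config.mu_center = center
    config.mu_scale = _MU_STD_TARGET / std
    return config


def encode_fd(state: FDState, config: FDConfig) -> np.ndarray:
    """Network input: centered/scaled position one-hot, motivation, and the
    optional θ channel.

    The 36 position channels are centered by the uniform mean 1/36 and scaled
    to unit variance each; the 4 motivation channels use the calibrated
    constants (variance 9 each).  In the motivation-blind control the four
    motivation channels are zero regardless of the true μ.
    """
    if config.mu_center is None:
        raise ValueError("config not calibrated; run calibrate_input_norm first")
    pos = np.full(_N_CELLS, -1.0 / _N_CELLS)
    r, c = state.position
    pos[r * GRID + c] += 1.0
    pos *= _POS_SCALE
    if config.motivation_blind:
        mu = np.zeros(N_ROOMS)
    else:
        mu = (state.mu - config.mu_center) * config.mu_scale
    parts = [pos, mu]
    if config.theta_as_input:
        tv = config.theta_input_value if config.theta_input_value is not None else config.theta[0]
        parts.append(np.array([(tv - _THETA_CENTER) / _THETA_SCALE]))  # var 9, like mu
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# training

def default_fd_schedule(n_steps: int = 400_000, gamma: float = 0.9) -> TrainSchedule:
    """Learning-rate 3e-3 → 3e-5, ε 0.5 → 0.05, both geometric per iteration."""
    return TrainSchedule(3e-3, 3e-5, n_steps, gamma, eps_start=0.5, eps_end=0.05)


def train_fd_agent(
    config: FDConfig,
    schedule: TrainSchedule | None = None,
    rng: np.random.Generator | None = None,
    eval_steps: int = 500,
    burn_in: int = 100,
    hidden: int = 100,
):
    """Train the 40(41)-100-100-100-5 sigmoid Q-network by semi-gradient TD.

    One continuing rollout of ``schedule.n_steps`` iterations with ε-greedy
    behavior; the TD error is backpropagated only through the selected
    action's output.  In the θ-as-input variant the cap is redrawn from 1..10
    every 10 iterations.  Returns the trained parameters and a log holding the
    greedy post-training rollout (room sequence, classification, rate).
    """
    if rng is None:
        rng = np.random.default_rng()
    if schedule is None:
        schedule = default_fd_schedule(gamma=config.gamma)
    if config.mu_center is None:
        calibrate_input_norm(config, rng)
    params = init_mlp(
        [config.n_inputs, hidden, hidden, hidden, len(ACTIONS)],
        ["sigmoid", "sigmoid", "sigmoid", "linear"],
        "xavier",
        rng,
        gain=[4.0, 4.0, 4.0, 1.0],  # sigmoid gain, keeps the deep trunk alive
    )
    params.input_spec = {
        "dim": config.n_inputs,
        "mu_center": config.mu_center.tolist(),
        "mu_scale": config.mu_scale.tolist(),
    }
    gamma = schedule.gamma
    state = FDState((int(rng.integers(GRID)), int(rng.integers(GRID))), np.zeros(N_ROOMS))
    for t in range(schedule.n_steps):
        if config.theta_as_input and t % 10 == 0:
            config.theta[:] = float(rng.integers(1, 11))
            config.theta_input_value = config.theta[0]
            state.mu = np.minimum(state.mu, config.theta)
        x = encode_fd(state, config)
        cache, q = forward(params, x)
        policy = PolicySpec("epsilon_greedy", epsilon=schedule.eps(t))
        a = select_action(q, policy, rng=rng)
        next_state, r = fd_step(config, state, ACTIONS[a])
        _, q_next = forward(params, encode_fd(next_state, config))
        delta = td_error(r, gamma, float(q_next.max()), float(q[a]))
        update_selected(params, cache, a, delta, schedule.lr(t))
        state = next_state

    rooms, rate = greedy_rollout(params, config, rng, eval_steps, burn_in)
    label = classify_strategy(rooms[burn_in:], config.theta)
    log = {
        "rooms": rooms,
        "burn_in": burn_in,
        "strategy": label.name,
        "empirical_rate": label.empirical_rate,
    }
    return params, log


def greedy_rollout(
    params: MLPParams,
    config: FDConfig,
    rng: np.random.Generator,
    n_steps: int = 500,
    burn_in: int = 100,
):
    """Deterministic (ε = 0) rollout; returns the room sequence and the mean
    subjective reward over the post-burn-in steps."""
    state = FDState((int(rng.integers(GRID)), int(rng.integers(GRID))), np.zeros(N_ROOMS))
    policy = PolicySpec("deterministic")
    rooms, rewards = [], []
    for _ in range(n_steps):
        _, q = forward(params, encode_fd(state, config))
        a = select_action(q, policy, rng=rng)
        state, r = fd_step(config, state, ACTIONS[a])
        rooms.append(room_of(state.position))
        rewards.append(r)
    rate = float(np.mean(rewards[burn_in:]))
    return rooms, rate


# ---------------------------------------------------------------------------
# analytic strategy rates and classification

def strategy_rate(strategy_name: str, theta) -> Fraction:
    """Closed-form mean subjective reward per step of a canonical strategy.

    Exact rational arithmetic; ``float()`` the result if needed.  The caps
    enter through min(θ, k): a component left unconsumed for k steps has grown
    to min(θ, k).
    """
    th = Fraction(theta)
    if th < 1:
        raise ValueError("theta must be >= 1")
    if strategy_name == "one_room_binge":
        return Fraction(1, 2)
    if strategy_name == "two_room_binge":
        return min(th, Fraction(1))
    if strategy_name == "delayed_two_room_binge":
        return 2 * min(th, Fraction(2)) / 3
    if strategy_name == "migration":
        return (min(th, Fraction(9)) + 1) / 3
    if strategy_name == "delayed_migration":
        return (3 * (min(th, Fraction(11)) + 1) + min(th, Fraction(9)) + 2) / 14
    raise ValueError(f"unknown strategy {strategy_name!r}")


def _cyclic_runs(period):
    """Run-length encoding of one period treated cyclically."""
    p = len(period)
    # rotate so index 0 starts a run
    start = 0
    for i in range(p):
        if period[i] != period[i - 1]:
            start = i
            break
    rot = period[start:] + period[:start]
    runs = []
    for room in rot:
        if runs and runs[-1][0] == room:
            runs[-1][1] += 1
        else:
            runs.append([room, 1])
    return [(room, n) for room, n in runs]


def classify_strategy(room_visit_sequence, theta, max_period: int = 14) -> StrategyLabel:
    """Label a room-occupancy sequence with the canonical strategy it follows.

    Detects the minimal period of the sequence and matches its cyclic
    run-length structure against the strategy templates; anything aperiodic or
    unrecognized is ``other``.  The empirical rate replays the sequence
    through the motivation dynamics from zero drives and averages the second
    half, so transients do not bias it.
    """
    seq = list(room_visit_sequence)
    if len(seq) < 2 * max_period:
        raise ValueError(f"need at least {2 * max_period} steps to classify")
    rewards = replay_rooms(seq, theta)
    rate = float(np.mean([float(r) for r in rewards[len(rewards) // 2 :]]))

    period = None
    for p in range(1, max_period + 1):
        if all(seq[i] == seq[i + p] for i in range(len(seq) - p)):
            period = p
            break
    name = "other"
    if period is not None:
        runs = _cyclic_runs(seq[:period])
        rooms = {room for room, _ in runs}
        lengths = sorted(n for _, n in runs)
        if period == 1:
            name = "one_room_binge"
        elif period == 2 and len(rooms) == 2:
            name = "two_room_binge"
        elif period == 3 and len(rooms) == 2 and lengths == [1, 2]:
            name = "delayed_two_room_binge"
        elif period == 12 and len(rooms) == 4 and lengths == [3, 3, 3, 3]:
            name = "migration"
        elif period == 14 and len(rooms) == 4 and lengths == [3, 3, 3, 5]:
            name = "delayed_migration"
    return StrategyLabel(name, rate)


_CANONICAL = {
    # start position, one period of actions; room changes go through doorways
    "one_room_binge": ((0, 0), ("stay",)),
    "two_room_binge": ((1, 2), ("right", "left")),
    "delayed_two_room_binge": ((1, 2), ("right", "stay", "left")),
    "migration": (
        (1, 2),
        ("right", "right", "down", "down", "down", "left", "left", "left",
         "up", "up", "up", "right"),
    ),
    "delayed_migration": (
        (1, 2),
        ("right", "right", "down", "down", "down", "left", "left", "left",
         "up", "up", "stay", "stay", "up", "right"),
    ),
}


def canonical_trajectory(strategy_name: str, n_periods: int = 1):
    """Start position and action sequence realizing a canonical strategy."""
    if strategy_name not in _CANONICAL:
        raise ValueError(f"unknown strategy {strategy_name!r}")
    start, actions = _CANONICAL[strategy_name]
    return start, actions * n_periods


def replay_canonical(strategy_name: str, theta, n_periods: int = 4):
    """Drive a canonical trajectory through ``fd_step`` and return the
    per-step (room, reward) pairs of the final two periods — the steady
    state.  Two periods because the reward cycle of the one-room binge
    (0, 1, 0, 1, …) is twice its one-action movement period.

    Rewards are exact (integers for integer caps) because the replay goes
    through the same elementwise update as the environment.
    """
    start, actions = canonical_trajectory(strategy_name)
    period = len(actions)
    config = FDConfig(theta)
    rooms_all = []
    state = FDState(start, np.zeros(N_ROOMS))
    for action in actions * n_periods:
        state, _ = fd_step(config, state, action)
        rooms_all.append(room_of(state.position))
    rewards = replay_rooms(rooms_all, theta)
    keep = 2 * period
    return list(zip(rooms_all[-keep:], rewards[-keep:]))


def steady_state_rate(strategy_name: str, theta) -> Fraction:
    """Mean reward per step over the steady-state cycle of the canonical
    trajectory, in exact rational arithmetic (the simulation-side oracle to
    ``strategy_rate``)."""
    pairs = replay_canonical(strategy_name, theta)
    total = sum(Fraction(r) for _, r in pairs)
    return total / len(pairs)


__all__.extend(["replay_canonical", "steady_state_rate", "default_fd_schedule"])


# ---------------------------------------------------------------------------
# addiction variant and the θ sweep

def make_addiction_config(gamma: float) -> FDConfig:
    """Caps (1, 1, 1, 10): rooms 1–3 saturate immediately, the fourth
    ("smoking") room builds motivation up to 10."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    return FDConfig(np.array([1.0, 1.0, 1.0, 10.0]), gamma=gamma)


def consumption_intervals(rooms, theta, room: int = 3):
    """Steps between successive consumptions (nonzero rewards) in one room.

    Used to quantify how long the addiction-variant agent stays away from the
    high-cap room between visits.
    """
    rewards = replay_rooms(rooms, theta)
    hits = [i for i, (rm, r) in enumerate(zip(rooms, rewards)) if rm == room and r > 0]
    return np.diff(hits) if len(hits) > 1 else np.array([], dtype=int)


def theta_sweep(n: int = 41, lo: float = 1.0, hi: float = 100.0) -> np.ndarray:
    """The geometric cap sweep used for the behavioral phase diagram."""
    return np.geomspace(lo, hi, n)
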