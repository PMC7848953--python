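"""Two-level manager-agent hierarchy on the transport network.

The trained transport agent acts on an *estimate* of its motivation that a
higher-level manager network maintains: at every step the manager observes
the agent's position and the current estimate, and either zeroes one
component or does nothing.  The manager is itself a Q-learner, trained either

* **supervised** — replaying prerecorded episodes of the agent running under
  the true motivation dynamics, rewarded +2 for predicting the true
  motivation transition and −2 otherwise (−1 when the wrong action was
  "do nothing"), or
* **unsupervised** — in the closed loop, rewarded +5 whenever the agent's
  environment reward is positive and −2/−1 otherwise, i.e. from the *sign*
  of the agent's reward only.

A correctly trained manager makes the hierarchy behave exactly like the flat
agent; the evaluation harness is shared with :mod:`motivnet.transport` so an
oracle manager is bit-identical to the agent-only run under the same seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nets import (
    GradAccumulator,
    MLPParams,
    PolicySpec,
    TrainSchedule,
    forward,
    init_mlp,
    select_action,
    update_selected,
)
from .transport import (
    TransportState,
    TransportWorld,
    encode_transport,
    evaluate_transport,
    sample_target_set,
    transport_step,
)

__all__ = [
    "ManagerRewardSchedule",
    "do_nothing_action",
    "apply_manager_action",
    "manager_reward",
    "encode_manager",
    "record_episodes",
    "train_manager",
    "OracleMotivation",
    "ManagerMotivation",
    "evaluate_hierarchy",
    "default_supervised_schedule",
    "default_unsupervised_schedule",
]


@dataclass
class ManagerRewardSchedule:
    """Reward schedule for the manager's actions.

    supervised: (+2, −2, −1); unsupervised: (+5, −2, −1).  The positive and
    negative magnitudes are balanced so the manager neither reinforces
    erroneous edits nor collapses to always doing nothing; the softened −1
    discourages erroneous edits more than missed ones.
    """

    mode: str
    r_correct: float
    r_incorrect: float
    r_incorrect_nothing: float

    @classmethod
    def supervised(cls) -> "ManagerRewardSchedule":
        return cls("supervised", 2.0, -2.0, -1.0)

    @classmethod
    def unsupervised(cls) -> "ManagerRewardSchedule":
        return cls("unsupervised", 5.0, -2.0, -1.0)


def do_nothing_action(n_cities: int) -> int:
    """Actions 0..n−1 zero that motivation component; action n does nothing."""
    return n_cities


def apply_manager_action(mu_est: np.ndarray, action: int) -> np.ndarray:
    """Zero the selected component, or return the estimate unchanged.

    Idempotent: applying the same action twice equals applying it once.
    """
    n = mu_est.shape[0]
    if not 0 <= action <= n:
        raise ValueError(f"manager action {action} out of range")
    out = mu_est.copy()
    if action < n:
        out[action] = 0.0
    return out


def manager_reward(
    schedule: ManagerRewardSchedule,
    action: int,
    mu_true_before: np.ndarray | None = None,
    mu_true_after: np.ndarray | None = None,
    agent_reward_sign: float | None = None,
) -> float:
    """Score one manager action under the given schedule.

    Supervised mode compares the action's effect on the true motivation with
    the true transition; unsupervised mode looks only at the sign of the
    agent's reward.
    """
    if schedule.mode == "supervised":
        if mu_true_before is None or mu_true_after is None:
            raise ValueError("supervised reward needs the true transition")
        before = np.asarray(mu_true_before, dtype=float)
        after = np.asarray(mu_true_after, dtype=float)
        changed = np.flatnonzero(before != after)
        # the unique correct action names the changed component, or does
        # nothing; zeroing an already-zero component counts as an error even
        # though it is a no-op, so the scoring has a single maximizer
        correct = do_nothing_action(before.shape[0]) if changed.size == 0 else int(changed[0])
        if action == correct:
            return schedule.r_correct
    elif schedule.mode == "unsupervised":
        if agent_reward_sign is None:
            raise ValueError("unsupervised reward needs the agent's reward sign")
        if agent_reward_sign > 0:
            return schedule.r_correct
    else:
        raise ValueError(f"unknown mode {schedule.mode!r}")
    n = (mu_true_before if mu_true_before is not None else np.empty(0)).shape[0]
    if mu_true_before is not None and action == do_nothing_action(n):
        return schedule.r_incorrect_nothing
    if schedule.mode == "unsupervised" and mu_true_before is None:
        raise ValueError("unsupervised reward needs mu_true_before for action arity")
    return schedule.r_incorrect


def encode_manager(city: int, mu_est: np.ndarray, n_cities: int) -> np.ndarray:
    """Manager input: agent position one-hot plus the motivation estimate."""
    return encode_transport(TransportState(city, mu_est), n_cities)


def record_episodes(
    world: TransportWorld,
    agent_params: MLPParams,
    n_episodes: int,
    rng: np.random.Generator,
    beta: float = 10.0,
    m_targets: int = 3,
    max_steps: int = 100,
    start_city: int | None = 0,
):
    """Prerecord trained-agent episodes under the true motivation dynamics.

    Episodes start at the origin city (``start_city=None`` for random
    starts) with random targets.  Each episode is a list of per-step records
    ``(position, mu_before, mu_after)`` at the manager's decision points: on
    arrival at ``position`` the true motivation goes from ``mu_before`` to
    ``mu_after`` (the arrival component zeroed if it was set).
    """
    n = world.n_cities
    policy = PolicySpec("softmax", beta=beta)
    episodes = []
    for _ in range(n_episodes):
        start = int(rng.integers(n)) if start_city is None else start_city
        targets = sample_target_set(world, start, rng, m_targets)
        mu = np.zeros(n)
        mu[targets] = 1.0
        state = TransportState(start, mu)
        steps = [(state.city, mu.copy(), mu.copy())]  # start is never a target
        for _ in range(max_steps):
            _, q = forward(agent_params, encode_transport(state, n))
            a = select_action(q, policy, world.adjacency[state.city], rng)
            mu_before = state.mu.copy()
            state, _, done = transport_step(world, state, a)
            steps.append((state.city, mu_before, state.mu.copy()))
            if done:
                break
        episodes.append(steps)
    return episodes


def default_supervised_schedule(n_episodes: int = 200_000) -> TrainSchedule:
    """Learning rate 1e-3 → 1e-6 geometric per episode, γ = 0.9."""
    return TrainSchedule(1e-3, 1e-6, n_episodes, 0.9)


def default_unsupervised_schedule(n_episodes: int = 200_000) -> TrainSchedule:
    """Learning rate 1e-2 → 1e-5 per episode, clipped at 1e-3 while the
    annealed value is larger; γ = 0.9."""
    return TrainSchedule(1e-2, 1e-5, n_episodes, 0.9)


def _init_manager(n_cities: int, rng, hidden: int = 200) -> MLPParams:
    # variance-preserving gain for the stacked leaky-ReLU trunk; with plain
    # Xavier the three hidden layers attenuate signal enough that single
    # output heads can stay mis-ranked ("zero city i" never overtaking
    # "do nothing" at city i) no matter how long training runs
    gain = float(np.sqrt(2.0 / (1.0 + 0.2**2)))
    params = init_mlp(
        [2 * n_cities, hidden, hidden, hidden, n_cities + 1],
        ["leaky_relu"] * 4,
        "xavier",
        rng,
        alpha=0.2,
        gain=[gain, gain, gain, 1.0],
    )
    params.input_spec = {"dim": 2 * n_cities, "n_cities": n_cities}
    return params


def train_manager(
    mode: str,
    world: TransportWorld,
    agent_params: MLPParams,
    schedule: TrainSchedule | None = None,
    rng: np.random.Generator | None = None,
    epsilon: float = 0.1,
    minibatch: int = 50,
    episode_cap: int = 50,
    agent_beta: float = 10.0,
    hidden: int = 200,
    start_city: int | None = 0,
) -> MLPParams:
    """Train the 20-200-200-200-11 manager Q-network.

    Supervised mode replays freshly recorded trained-agent episodes (teacher
    forcing: the manager always sees the true motivation next step, whatever
    action it took, and is rewarded by comparing its edit with the true
    transition).  Unsupervised mode runs the closed loop — manager edits the
    estimate, the agent acts on it, the sign of the agent's true reward
    rewards the manager — with episodes hard-capped at ``episode_cap`` steps
    and semi-gradients accumulated over ``minibatch`` manager steps before
    each (averaged) weight update.  ε-greedy ε = 0.1 throughout; γ = 0.9.
    """
    if mode not in ("supervised", "unsupervised"):
        raise ValueError(f"unknown mode {mode!r}")
    if agent_params is None:
        raise ValueError("train the agent before the manager")
    if rng is None:
        rng = np.random.default_rng()
    if schedule is None:
        schedule = (
            default_supervised_schedule()
            if mode == "supervised"
            else default_unsupervised_schedule()
        )
    n = world.n_cities
    nothing = do_nothing_action(n)
    params = _init_manager(n, rng, hidden)
    policy = PolicySpec("epsilon_greedy", epsilon=epsilon)
    gamma = schedule.gamma
    reward_schedule = (
        ManagerRewardSchedule.supervised()
        if mode == "supervised"
        else ManagerRewardSchedule.unsupervised()
    )

    if mode == "supervised":
        for ep in range(schedule.n_steps):
            lr = schedule.lr(ep)
            steps = record_episodes(world, agent_params, 1, rng, start_city=start_city)[0]
            for t in range(len(steps)):
                city, mu_before, mu_after = steps[t]
                x = encode_manager(city, mu_before, n)
                cache, q = forward(params, x)
                a = select_action(q, policy, rng=rng)
                r = manager_reward(reward_schedule, a, mu_before, mu_after)
                if t + 1 < len(steps):
                    nc, nb, _ = steps[t + 1]
                    _, q_next = forward(params, encode_manager(nc, nb, n))
                    target = r + gamma * float(q_next.max())
                else:
                    target = r
                update_selected(params, cache, a, target - q[a], lr)
        return params

    # unsupervised: closed loop with minibatched updates.  An episode ends
    # when the *estimate* empties — the belief is the only motivation signal
    # the manager-agent system has, so its stopping rule lives on the belief
    # (the hard cap catches runs the manager fails to wind down).
    agent_policy = PolicySpec("softmax", beta=agent_beta)
    acc = GradAccumulator(params)
    lr = schedule.lr(0)
    for ep in range(schedule.n_steps):
        lr = min(schedule.lr(ep), 1e-3)
        start = int(rng.integers(n)) if start_city is None else start_city
        targets = sample_target_set(world, start, rng)
        mu_true = np.zeros(n)
        mu_true[targets] = 1.0
        state = TransportState(start, mu_true)
        mu_est = mu_true.copy()  # initial estimate matches the true targets
        for _ in range(episode_cap):
            x = encode_manager(state.city, mu_est, n)
            cache, q = forward(params, x)
            a = select_action(q, policy, rng=rng)
            mu_est = apply_manager_action(mu_est, a)
            if not mu_est.any():
                # the system believes it is done; terminal for the manager
                r = manager_reward(
                    reward_schedule, a, mu_true_before=mu_est, agent_reward_sign=-1.0
                )
                acc.add(params, cache, a, float(r - q[a]))
                if acc.count >= minibatch:
                    acc.apply_(params, lr, average=False)
                break
            _, q_agent = forward(
                agent_params, encode_transport(TransportState(state.city, mu_est), n)
            )
            move = select_action(q_agent, agent_policy, world.adjacency[state.city], rng)
            next_state, agent_r, _ = transport_step(world, state, move)
            r = manager_reward(
                reward_schedule, a, mu_true_before=mu_est, agent_reward_sign=agent_r
            )
            _, q_next = forward(params, encode_manager(next_state.city, mu_est, n))
            delta = r + gamma * float(q_next.max()) - q[a]
            acc.add(params, cache, a, float(delta))
            if acc.count >= minibatch:
                acc.apply_(params, lr, average=False)
            state = next_state
    acc.apply_(params, lr, average=False)
    return params


class OracleMotivation:
    """Motivation provider that exposes the true dynamics (the flat agent)."""

    def reset(self, state: TransportState) -> None:
        pass

    def estimate(self, state: TransportState) -> np.ndarray:
        return state.mu


class ManagerMotivation:
    """Motivation provider backed by a trained manager network (ε = 0).

    Maintains its own binary estimate across the episode; the manager can
    only zero components, so the estimate is non-increasing.
    """

    def __init__(self, manager_params: MLPParams, n_cities: int):
        self.params = manager_params
        self.n = n_cities
        self.mu_est = None

    def reset(self, state: TransportState) -> None:
        self.mu_est = state.mu.copy()

    def estimate(self, state: TransportState) -> np.ndarray:
        x = encode_manager(state.city, self.mu_est, self.n)
        _, q = forward(self.params, x)
        self.mu_est = apply_manager_action(self.mu_est, int(np.argmax(q)))
        return self.mu_est


def evaluate_hierarchy(
    world: TransportWorld,
    agent_params: MLPParams,
    manager_params: MLPParams | None,
    test_sets,
    rng: np.random.Generator,
    beta: float = 10.0,
):
    """Closed-loop evaluation: deterministic manager driving the softmax(β)
    agent on the shared test harness.

    ``manager_params=None`` runs the oracle (true-dynamics) manager, which is
    bit-identical to the agent-only evaluation under the same rng state.
    Returns the same metrics dict as ``evaluate_transport``.
    """
    provider = (
        OracleMotivation()
        if manager_params is None
        else ManagerMotivation(manager_params, world.n_cities)
    )
    return evaluate_transport(
        world, agent_params, test_sets, rng, beta, motivation_provider=provider
    )
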