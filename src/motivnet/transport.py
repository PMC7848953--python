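"""Transport-network routing with binary motivations.

Cities are sampled in the plane, roads are the Delaunay triangulation, and an
episode asks the agent to visit three target cities (order free, no return to
origin) while paying each road's Euclidean length.  Visiting a city whose
binary motivation component is set pays +5 and clears that component; the
episode ends when all components are zero, so the undiscounted return is
15 − (traveled length) and return maximization is length minimization.

``shortest_tour`` is the exact oracle: the minimum over the 3! target
orderings of chained shortest-path distances.  The Q-agent is a one-hidden-
layer leaky-ReLU network over (position one-hot, motivation) trained by
semi-gradient TD with a softmax behavior policy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import Delaunay, QhullError

from .nets import (
    MLPParams,
    PolicySpec,
    TrainSchedule,
    forward,
    init_mlp,
    select_action,
    update_selected,
)

__all__ = [
    "TransportWorld",
    "TransportState",
    "sample_world",
    "world_from_coords",
    "shortest_tour",
    "tour_length_state_space",
    "transport_step",
    "encode_transport",
    "default_transport_schedule",
    "train_transport",
    "sample_target_set",
    "run_transport_episode",
    "evaluate_transport",
    "world_to_dict",
    "world_from_dict",
    "REWARD_PER_TARGET",
]

REWARD_PER_TARGET = 5.0


@dataclass
class TransportWorld:
    """City coordinates, Delaunay road graph and all-pairs shortest paths."""

    coords: np.ndarray  # (n, 2)
    adjacency: np.ndarray  # (n, n) bool, symmetric
    edge_length: np.ndarray  # (n, n) float, 0 where no edge
    dist: np.ndarray  # all-pairs shortest-path distances
    predecessors: np.ndarray  # scipy csgraph predecessor matrix

    @property
    def n_cities(self) -> int:
        return self.coords.shape[0]

    def neighbors(self, city: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[city])

    def path(self, a: int, b: int) -> list:
        """Expand one shortest path a→b from the predecessor structure."""
        if a == b:
            return [a]
        out = [b]
        while out[-1] != a:
            p = int(self.predecessors[a, out[-1]])
            if p < 0:
                raise ValueError("graph not connected")
            out.append(p)
        return out[::-1]


@dataclass
class TransportState:
    city: int
    mu: np.ndarray  # (n,) binary motivation; episode over when all zero


def world_from_coords(coords: np.ndarray) -> TransportWorld:
    """Build the road graph (Delaunay edges, Euclidean lengths) and its
    all-pairs shortest paths for fixed city coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    tri = Delaunay(coords)
    adjacency = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            adjacency[a, b] = adjacency[b, a] = True
    edge_length = np.zeros((n, n))
    idx = np.nonzero(adjacency)
    edge_length[idx] = np.linalg.norm(coords[idx[0]] - coords[idx[1]], axis=1)
    graph = np.where(adjacency, edge_length, 0.0)
    dist, pred = shortest_path(
        graph, method="D", directed=False, return_predecessors=True
    )
    if not np.all(np.isfinite(dist)):
        raise ValueError("road graph is not connected")
    return TransportWorld(coords, adjacency, edge_length, dist, pred)


def sample_world(
    n_cities: int = 10, rng: np.random.Generator | None = None, max_resamples: int = 100
) -> TransportWorld:
    """Sample city coordinates from the standard normal and triangulate.

    Degenerate draws (collinear points, Qhull failures) are resampled.
    """
    if n_cities < 3:
        raise ValueError("need at least 3 cities for a triangulation")
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_resamples):
        coords = rng.standard_normal((n_cities, 2))
        try:
            return world_from_coords(coords)
        except (QhullError, ValueError):
            continue
    raise RuntimeError("could not draw a non-degenerate city layout")


def sample_target_set(
    world: TransportWorld, start: int, rng: np.random.Generator, m: int = 3
) -> np.ndarray:
    """m distinct target cities, excluding the start city."""
    others = np.array([c for c in range(world.n_cities) if c != start])
    return rng.choice(others, size=m, replace=False)


def shortest_tour(world: TransportWorld, start: int, targets):
    """Shortest open tour visiting all targets, as (length, city sequence).

    Minimum over target orderings of chained shortest-path distances; ties
    broken by lexicographic order of the expanded city sequence.
    """
    targets = sorted(set(int(t) for t in targets))
    best = None
    for order in permutations(targets):
        length = world.dist[start, order[0]]
        for a, b in zip(order, order[1:]):
            length += world.dist[a, b]
        seq = world.path(start, order[0])
        for a, b in zip(order, order[1:]):
            seq += world.path(a, b)[1:]
        key = (length, seq)
        if best is None or key < best:
            best = key
    return float(best[0]), best[1]


def tour_length_state_space(world: TransportWorld, start: int, targets) -> float:
    """Independent oracle: Dijkstra over the (city, visited-targets) state
    space, walking the road graph edge by edge.  Used to cross-check
    ``shortest_tour`` on small worlds."""
    targets = sorted(set(int(t) for t in targets))
    t_index = {t: i for i, t in enumerate(targets)}
    full = (1 << len(targets)) - 1

    def visit_bit(mask, city):
        if city in t_index:
            mask |= 1 << t_index[city]
        return mask

    start_mask = visit_bit(0, start)
    heap = [(0.0, start, start_mask)]
    seen = {}
    while heap:
        d, city, mask = heapq.heappop(heap)
        if mask == full:
            return d
        if seen.get((city, mask), np.inf) <= d:
            continue
        seen[(city, mask)] = d
        for nb in world.neighbors(city):
            nd = d + world.edge_length[city, nb]
            nmask = visit_bit(mask, int(nb))
            if seen.get((int(nb), nmask), np.inf) > nd:
                heapq.heappush(heap, (nd, int(nb), nmask))
    raise ValueError("targets unreachable")


def transport_step(world: TransportWorld, state: TransportState, action_city: int):
    """Move along one road; return ``(next_state, reward, done)``.

    Reward is +5 if the entered city's motivation component is set (then it
    clears), minus the road length either way.  Done when all components are
    zero.
    """
    action_city = int(action_city)
    if not world.adjacency[state.city, action_city]:
        raise ValueError(f"city {action_city} not adjacent to {state.city}")
    reward = -world.edge_length[state.city, action_city]
    mu = state.mu.copy()
    if mu[action_city] > 0:
        reward += REWARD_PER_TARGET
        mu[action_city] = 0
    next_state = TransportState(action_city, mu)
    return next_state, float(reward), bool(not mu.any())


def encode_transport(state: TransportState, n_cities: int) -> np.ndarray:
    """Input vector: position one-hot followed by the binary motivation."""
    x = np.zeros(2 * n_cities)
    x[state.city] = 1.0
    x[n_cities:] = state.mu
    return x


def default_transport_schedule(n_episodes: int = 100_000) -> TrainSchedule:
    """Learning rate 1e-2 → 1e-4 geometric per episode, γ = 0.9."""
    return TrainSchedule(1e-2, 1e-4, n_episodes, 0.9)


def train_transport(
    world: TransportWorld,
    schedule: TrainSchedule | None = None,
    rng: np.random.Generator | None = None,
    beta: float = 0.5,
    hidden: int = 200,
    m_targets: int = 3,
    max_steps: int = 400,
    start_city: int | None = 0,
) -> MLPParams:
    """Train the 20-200-10 leaky-ReLU Q-network by semi-gradient TD.

    Each episode starts at the origin city (``start_city``; pass None for a
    uniformly random start) with a fresh random target set; behavior is
    softmax(β = 0.5) over the Q-values of adjacent cities; the TD target
    maxes over the next city's adjacent actions.  The learning rate anneals
    per episode.
    """
    if rng is None:
        rng = np.random.default_rng()
    if schedule is None:
        schedule = default_transport_schedule()
    n = world.n_cities
    params = init_mlp(
        [2 * n, hidden, n], ["leaky_relu", "leaky_relu"], "xavier", rng, alpha=0.2
    )
    params.input_spec = {"dim": 2 * n, "n_cities": n}
    policy = PolicySpec("softmax", beta=beta)
    gamma = schedule.gamma
    for ep in range(schedule.n_steps):
        lr = schedule.lr(ep)
        start = int(rng.integers(n)) if start_city is None else start_city
        targets = sample_target_set(world, start, rng, m_targets)
        mu = np.zeros(n)
        mu[targets] = 1.0
        state = TransportState(start, mu)
        for _ in range(max_steps):
            x = encode_transport(state, n)
            cache, q = forward(params, x)
            a = select_action(q, policy, world.adjacency[state.city], rng)
            next_state, r, done = transport_step(world, state, a)
            if done:
                target = r
            else:
                _, q_next = forward(params, encode_transport(next_state, n))
                target = r + gamma * q_next[world.adjacency[next_state.city]].max()
            update_selected(params, cache, a, target - q[a], lr)
            state = next_state
            if done:
                break
    return params


def run_transport_episode(
    world: TransportWorld,
    params: MLPParams,
    start: int,
    targets,
    rng: np.random.Generator,
    beta: float = 10.0,
    motivation_provider=None,
    max_steps: int = 200,
):
    """Roll out one evaluation episode under softmax(β) over adjacent cities.

    ``motivation_provider`` supplies the motivation vector the *network* sees
    each step (defaults to the true dynamics); the environment itself always
    runs on the true motivation, and the episode counts as done only when
    every true target has been visited — a manager whose estimate goes wrong
    pays for it in traveled length, up to the step cap.  Returns (traveled
    length, city sequence, done flag).
    """
    n = world.n_cities
    mu = np.zeros(n)
    mu[np.asarray(targets)] = 1.0
    state = TransportState(int(start), mu)
    if motivation_provider is not None:
        motivation_provider.reset(state)
    policy = PolicySpec("softmax", beta=beta)
    traveled = 0.0
    route = [state.city]
    for _ in range(max_steps):
        if motivation_provider is None:
            mu_seen = state.mu
        else:
            mu_seen = motivation_provider.estimate(state)
        _, q = forward(params, encode_transport(TransportState(state.city, mu_seen), n))
        a = select_action(q, policy, world.adjacency[state.city], rng)
        next_state, _, done = transport_step(world, state, a)
        traveled += world.edge_length[state.city, a]
        route.append(int(a))
        state = next_state
        if done:
            return traveled, route, True
    return traveled, route, False


def evaluate_transport(
    world: TransportWorld,
    params: MLPParams,
    test_sets,
    rng: np.random.Generator,
    beta: float = 10.0,
    motivation_provider=None,
    rel_tol: float = 1e-9,
):
    """Compare rollout route lengths with the shortest-tour oracle.

    ``test_sets`` is a sequence of (start, targets) pairs.  Returns a dict
    with the fraction of episodes matching the oracle length (relative
    tolerance 1e-9: both lengths are sums from the same edge table), the mean
    percent excess 100·mean((L − L*)/L*), and the raw (L, L*) pairs.
    """
    pairs = []
    n_done = 0
    for start, targets in test_sets:
        l_star, _ = shortest_tour(world, start, targets)
        traveled, _, done = run_transport_episode(
            world, params, start, targets, rng, beta, motivation_provider
        )
        n_done += done
        pairs.append((traveled, l_star))
    arr = np.array(pairs)
    excess = (arr[:, 0] - arr[:, 1]) / arr[:, 1]
    optimal = np.abs(arr[:, 0] - arr[:, 1]) <= rel_tol * arr[:, 1]
    return {
        "fraction_optimal": float(np.mean(optimal)),
        "mean_percent_excess": float(100.0 * np.mean(excess)),
        "pairs": arr,
        "fraction_completed": n_done / len(pairs),
    }


def make_test_sets(
    world, n_sets: int, rng: np.random.Generator, m: int = 3,
    start_city: int | None = 0,
):
    """Fresh random (start, targets) evaluation pairs.

    By default every episode starts at the origin city, matching training;
    pass ``start_city=None`` for uniformly random starts.
    """
    out = []
    for _ in range(n_sets):
        start = int(rng.integers(world.n_cities)) if start_city is None else start_city
        out.append((start, sample_target_set(world, start, rng, m)))
    return out


__all__.append("make_test_sets")


# ---------------------------------------------------------------------------
# serialization (JSON-friendly dicts; cli_io writes them out)

def world_to_dict(world: TransportWorld) -> dict:
    edges = [
        [int(a), int(b), float(world.edge_length[a, b])]
        for a, b in zip(*np.nonzero(np.triu(world.adjacency)))
    ]
    return {"coords": world.coords.tolist(), "edges": edges}


def world_from_dict(d: dict) -> TransportWorld:
    return world_from_coords(np.asarray(d["coords"]))
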