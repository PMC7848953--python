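"""Experiment configuration, artifacts and fixtures.

An :class:`ExperimentConfig` is a plain YAML-serializable record of one run:
the experiment kind, its environment parameters, the training schedule, the
seed, and the output directory.  ``run_experiment`` dispatches to the
module-level train/eval operations and writes versioned artifacts (weights,
logs, metrics) under the output directory; identical config + seed yields
bit-identical metrics.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .nets import TrainSchedule, save_params

__all__ = [
    "ExperimentConfig",
    "RunArtifacts",
    "load_config",
    "save_config",
    "config_hash",
    "run_experiment",
    "make_fixtures",
]

KINDS = ("four_demands", "transport", "hrl", "pavlovian")


@dataclass
class ExperimentConfig:
    """One experiment: kind, environment parameters, schedule, seed, output.

    ``env`` and ``schedule`` are flat mappings of plain scalars so the whole
    config round-trips losslessly through YAML.
    """

    kind: str
    seed: int
    out_dir: str
    env: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        validator = _VALIDATORS[self.kind]
        validator(self.env)


def _validate_four_demands(env: dict) -> None:
    theta = env.get("theta", 1.0)
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    if np.any(thetas < 1):
        raise ValueError("theta caps must be >= 1")
    gamma = env.get("gamma", 0.9)
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")


def _validate_transport(env: dict) -> None:
    if env.get("n_cities", 10) < 3:
        raise ValueError("need at least 3 cities")


def _validate_hrl(env: dict) -> None:
    _validate_transport(env)
    if env.get("mode", "supervised") not in ("supervised", "unsupervised"):
        raise ValueError("hrl mode must be supervised or unsupervised")


def _validate_pavlovian(env: dict) -> None:
    if env.get("gamma", 0.9) <= 0:
        raise ValueError("gamma must be positive")


_VALIDATORS = {
    "four_demands": _validate_four_demands,
    "transport": _validate_transport,
    "hrl": _validate_hrl,
    "pavlovian": _validate_pavlovian,
}


@dataclass
class RunArtifacts:
    """Paths of the files one run produced, plus its headline metrics."""

    config_path: str
    weights: list
    logs: list
    metrics: dict


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig(**yaml.safe_load(fh))


def config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(config: ExperimentConfig) -> dict:
    return {"motivnet_version": __version__, "config_hash": config_hash(config)}


def _write_json(path, payload: dict, config: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        json.dump({**_stamp(config), **payload}, fh, indent=1)


def _write_metrics_csv(path, rows, header, config: ExperimentConfig) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"# motivnet {__version__} config {config_hash(config)}"])
        writer.writerow(header)
        writer.writerows(rows)


def _schedule_from(config: ExperimentConfig, defaults: TrainSchedule) -> TrainSchedule:
    s = config.schedule
    return TrainSchedule(
        s.get("lr_start", defaults.lr_start),
        s.get("lr_end", defaults.lr_end),
        int(s.get("n_steps", defaults.n_steps)),
        s.get("gamma", defaults.gamma),
        s.get("eps_start", defaults.eps_start),
        s.get("eps_end", defaults.eps_end),
    )


def run_experiment(config: ExperimentConfig) -> RunArtifacts:
    """Run one experiment end to end and write its artifacts.

    Deterministic: the same config and seed produce bit-identical metrics
    files (modulo the version stamp).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.yaml"
    save_config(config, cfg_path)
    rng = np.random.default_rng(config.seed)
    runner = _RUNNERS[config.kind]
    weights, logs, metrics = runner(config, out, rng)
    _write_json(out / "metrics.json", {"metrics": metrics}, config)
    logs = [str(p) for p in logs] + [str(out / "metrics.json")]
    return RunArtifacts(str(cfg_path), [str(p) for p in weights], logs, metrics)


def _run_four_demands(config: ExperimentConfig, out: Path, rng):
    from .four_demands import FDConfig, default_fd_schedule, train_fd_agent

    env = config.env
    fd = FDConfig(
        np.asarray(env.get("theta", 1.0), dtype=float),
        gamma=env.get("gamma", 0.9),
        theta_as_input=env.get("theta_as_input", False),
        motivation_blind=env.get("motivation_blind", False),
    )
    schedule = _schedule_from(config, default_fd_schedule(gamma=fd.gamma))
    params, log = train_fd_agent(fd, schedule, rng)
    wpath = out / "agent.npz"
    save_params(params, wpath)
    lpath = out / "rollout.json"
    _write_json(
        lpath,
        {"rooms": log["rooms"], "strategy": log["strategy"],
         "empirical_rate": log["empirical_rate"]},
        config,
    )
    metrics = {"strategy": log["strategy"], "empirical_rate": log["empirical_rate"]}
    return [wpath], [lpath], metrics


def _run_transport(config: ExperimentConfig, out: Path, rng):
    from .transport import (
        default_transport_schedule,
        evaluate_transport,
        make_test_sets,
        sample_world,
        train_transport,
        world_to_dict,
    )

    env = config.env
    world = sample_world(env.get("n_cities", 10), rng)
    schedule = _schedule_from(config, default_transport_schedule())
    params = train_transport(world, schedule, rng)
    tests = make_test_sets(world, env.get("n_test_sets", 100), rng)
    m = evaluate_transport(world, params, tests, rng, beta=env.get("eval_beta", 10.0))
    wpath = out / "agent.npz"
    save_params(params, wpath)
    worldpath = out / "world.json"
    _write_json(worldpath, world_to_dict(world), config)
    rows = [(f"{L:.9f}", f"{Ls:.9f}") for L, Ls in m["pairs"]]
    cpath = out / "test_lengths.csv"
    _write_metrics_csv(cpath, rows, ["traveled", "shortest"], config)
    metrics = {
        "fraction_optimal": m["fraction_optimal"],
        "mean_percent_excess": m["mean_percent_excess"],
    }
    return [wpath], [worldpath, cpath], metrics


def _run_hrl(config: ExperimentConfig, out: Path, rng):
    from .hrl import evaluate_hierarchy, train_manager
    from .transport import (
        default_transport_schedule,
        make_test_sets,
        sample_world,
        train_transport,
    )

    env = config.env
    world = sample_world(env.get("n_cities", 10), rng)
    agent = train_transport(
        world,
        _schedule_from(config, default_transport_schedule()),
        rng,
    )
    mode = env.get("mode", "supervised")
    from .hrl import default_supervised_schedule, default_unsupervised_schedule

    msched = (
        default_supervised_schedule(int(env.get("manager_episodes", 200_000)))
        if mode == "supervised"
        else default_unsupervised_schedule(int(env.get("manager_episodes", 200_000)))
    )
    manager = train_manager(mode, world, agent, msched, rng)
    tests = make_test_sets(world, env.get("n_test_sets", 100), rng)
    m = evaluate_hierarchy(world, agent, manager, tests, rng)
    apath, mpath = out / "agent.npz", out / "manager.npz"
    save_params(agent, apath)
    save_params(manager, mpath)
    rows = [(f"{L:.9f}", f"{Ls:.9f}") for L, Ls in m["pairs"]]
    cpath = out / "hierarchy_lengths.csv"
    _write_metrics_csv(cpath, rows, ["traveled", "shortest"], config)
    metrics = {
        "mode": mode,
        "fraction_optimal": m["fraction_optimal"],
        "mean_percent_excess": m["mean_percent_excess"],
    }
    return [apath, mpath], [cpath], metrics


def _run_pavlovian(config: ExperimentConfig, out: Path, rng):
    from .pavlovian import (
        TRIAL_TYPES,
        default_rnn_schedule,
        expected_value_trace,
        make_trial,
        rnn_forward,
        train_rnn,
        trial_mse,
        v_star,
    )

    env = config.env
    schedule = _schedule_from(config, default_rnn_schedule())
    params, losses = train_rnn(
        schedule, rng, motivation_blind=env.get("motivation_blind", False)
    )
    wpath = out / "rnn.npz"
    np.savez_compressed(wpath, w_in=params.w_in, w_rec=params.w_rec, w_out=params.w_out)
    rows = []
    for spec in TRIAL_TYPES:
        trial = make_trial(spec)
        trace = rnn_forward(params, trial)
        vs = v_star(trial, schedule.gamma)
        for t in range(len(vs)):
            rows.append(
                (spec.name, t + 1, trial.cue[t], trial.motivation[t],
                 trial.reward[t], f"{trace.v[t]:.6f}", f"{vs[t]:.6f}")
            )
    cpath = out / "traces.csv"
    _write_metrics_csv(
        cpath, rows, ["trial", "step", "cue", "motivation", "reward", "v", "v_star"],
        config,
    )
    metrics = {"mse_fixed_point": trial_mse(params, schedule.gamma),
               "final_loss": float(losses[-1])}
    return [wpath], [cpath], metrics


_RUNNERS = {
    "four_demands": _run_four_demands,
    "transport": _run_transport,
    "hrl": _run_hrl,
    "pavlovian": _run_pavlovian,
}


# ---------------------------------------------------------------------------
# fixtures: miniature deterministic instances for tests and examples

def make_fixtures(rng: np.random.Generator | None = None) -> dict:
    """Deterministic miniature instances.

    * a 7-city world with exhaustively verified shortest-tour lengths,
    * the canonical Four Demands trajectories with their exact rates,
    * a tiny hand-weighted 2-unit value RNN with a hand-unrolled trace.
    """
    from .four_demands import STRATEGIES, canonical_trajectory, strategy_rate
    from .pavlovian import RNNParams, TrialSpec, make_trial, rnn_forward
    from .transport import sample_world, sample_target_set, shortest_tour, \
        tour_length_state_space

    if rng is None:
        rng = np.random.default_rng(7)
    world = sample_world(7, rng)
    tours = []
    for _ in range(10):
        start = int(rng.integers(7))
        targets = sample_target_set(world, start, rng)
        length, seq = shortest_tour(world, start, targets)
        assert abs(length - tour_length_state_space(world, start, targets)) < 1e-9
        tours.append({"start": start, "targets": sorted(int(t) for t in targets),
                      "length": length, "route": seq})

    strategies = {
        name: {
            "start": canonical_trajectory(name)[0],
            "actions": list(canonical_trajectory(name)[1]),
            "rate_theta_100": float(strategy_rate(name, 100)),
        }
        for name in STRATEGIES
    }

    w_in = np.array([[0.5, -0.25, 0.1], [-0.3, 0.4, 0.2]])
    w_rec = np.array([[0.2, -0.1], [0.05, 0.3]])
    w_out = np.array([1.5, -0.7])
    tiny = RNNParams(w_in, w_rec, w_out)
    trace = rnn_forward(tiny, make_trial(TrialSpec(1, 1.0)))
    return {
        "world": world,
        "tours": tours,
        "strategies": strategies,
        "tiny_rnn": tiny,
        "tiny_rnn_trace": trace,
    }
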