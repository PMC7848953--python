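"""Recurrent value network for Pavlovian conditioning with motivation blocks.

Each 20-step trial presents a cue (conditioned stimulus) in steps 6–10 and a
subjective reward (unconditioned stimulus) in steps 14–18 (1-based).  Trials
come in six types: strong/weak/zero reward and strong/weak/zero punishment,
with signed cue and US magnitudes 0, ±0.5, ±1 (US = cue value, because the
subjective reward is the product of the positive outcome size and the ±1
motivation).  A constant motivation input (+1 in reward blocks, −1 in
punishment blocks) is the only way to tell the two zero-magnitude trial
types apart.

A 40-unit sigmoid recurrent network reads (cue, motivation, subjective
reward) and outputs a scalar value estimate V_t; it is trained by TD(0)
with γ = 0.9, backpropagating the TD errors through time.  The input
weights stay frozen at their random initialization — only the recurrent
and readout weights learn.  Feeding the reward trace as an input matters:
it is what lets type-specific activity appear in the hidden state at
outcome time, from which TD bootstrapping can grow the recurrent memory
that carries the cue across the delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nets import TrainSchedule, anneal

__all__ = [
    "N_STEPS",
    "CUE_WINDOW",
    "US_WINDOW",
    "TRIAL_TYPES",
    "TrialSpec",
    "TrialTensors",
    "RNNParams",
    "RNNTrace",
    "make_trial",
    "blind_trial",
    "v_star",
    "expected_value_trace",
    "rnn_forward",
    "init_rnn",
    "default_rnn_schedule",
    "train_rnn",
    "trial_mse",
]

N_STEPS = 20
CUE_WINDOW = slice(5, 10)  # 0-based; steps 6-10 of 20, 1-based
US_WINDOW = slice(13, 18)  # steps 14-18 of 20, 1-based
N_HIDDEN = 40
MAGNITUDES = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class TrialSpec:
    """One of the six trial types: valence ±1, magnitude 0 / 0.5 / 1."""

    valence: int  # +1 reward block, -1 punishment block
    magnitude: float

    def __post_init__(self):
        if self.valence not in (-1, 1):
            raise ValueError("valence must be +1 or -1")
        if self.magnitude not in MAGNITUDES:
            raise ValueError(f"magnitude must be one of {MAGNITUDES}")

    @property
    def name(self) -> str:
        kind = {0.0: "zero", 0.5: "weak", 1.0: "strong"}[self.magnitude]
        block = "reward" if self.valence > 0 else "punishment"
        return f"{kind}_{block}"


TRIAL_TYPES = tuple(
    TrialSpec(v, m) for v in (1, -1) for m in MAGNITUDES
)


@dataclass
class TrialTensors:
    """20-step cue, motivation and subjective-reward traces of one trial."""

    cue: np.ndarray
    motivation: np.ndarray
    reward: np.ndarray


def make_trial(spec: TrialSpec) -> TrialTensors:
    """Build the input/reward traces for one trial type.

    The signed cue and US values coincide (valence·magnitude); the two
    zero-magnitude trial types therefore have identical cue and reward
    traces and differ only in the constant motivation input.
    """
    signed = spec.valence * spec.magnitude
    cue = np.zeros(N_STEPS)
    cue[CUE_WINDOW] = signed
    reward = np.zeros(N_STEPS)
    reward[US_WINDOW] = signed
    motivation = np.full(N_STEPS, float(spec.valence))
    return TrialTensors(cue, motivation, reward)


def blind_trial(trial: TrialTensors) -> TrialTensors:
    """The same trial as seen by a motivation-blinded network: the
    motivation input channel is zeroed, rewards untouched."""
    return TrialTensors(trial.cue.copy(), np.zeros(N_STEPS), trial.reward.copy())


def v_star(trial: TrialTensors, gamma: float = 0.9) -> np.ndarray:
    """Ground-truth value trace: V*_t = Σ_{τ≥0} γ^τ · r_{t+τ} within the
    trial (the current step's reward is included)."""
    v = np.zeros(N_STEPS)
    nxt = 0.0
    for t in range(N_STEPS - 1, -1, -1):
        nxt = trial.reward[t] + gamma * nxt
        v[t] = nxt
    return v


def expected_value_trace(spec: TrialSpec, gamma: float = 0.9) -> np.ndarray:
    """The TD fixed point for this trial type.

    Before cue onset the three same-valence trial types are
    indistinguishable from the network's inputs, so the learnable value
    there is the magnitude-average of their V*; from cue onset onward the
    trial type is observable and the fixed point is the trial's own V*.
    """
    own = v_star(make_trial(spec), gamma)
    pre = np.mean(
        [v_star(make_trial(TrialSpec(spec.valence, m)), gamma) for m in MAGNITUDES],
        axis=0,
    )
    out = own.copy()
    out[: CUE_WINDOW.start] = pre[: CUE_WINDOW.start]
    return out


# ---------------------------------------------------------------------------
# the recurrent network

@dataclass
class RNNParams:
    """Input, recurrent and readout weights of the value RNN.

    ``w_in`` (40×2, Xavier) is frozen; ``w_rec`` (40×40) and ``w_out`` (40)
    start at U(−1e−5, 1e−5) and are the trained parameters.
    """

    w_in: np.ndarray
    w_rec: np.ndarray
    w_out: np.ndarray


@dataclass
class RNNTrace:
    hidden: np.ndarray  # (20, 40) sigmoid activations, entries in (0, 1)
    v: np.ndarray  # (20,) value output


N_INPUTS = 3  # cue, motivation, subjective reward


def init_rnn(rng: np.random.Generator, n_hidden: int = N_HIDDEN) -> RNNParams:
    lim = np.sqrt(6.0 / (N_INPUTS + n_hidden))
    w_in = rng.uniform(-lim, lim, size=(n_hidden, N_INPUTS))
    w_rec = rng.uniform(-1e-5, 1e-5, size=(n_hidden, n_hidden))
    w_out = rng.uniform(-1e-5, 1e-5, size=n_hidden)
    return RNNParams(w_in, w_rec, w_out)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def rnn_forward(params: RNNParams, trial: TrialTensors) -> RNNTrace:
    """Unroll the network over one trial: h_t = σ(W_in x_t + W_rec h_{t−1})
    with h_0 = 0, v_t = w_out·h_t; x_t = (cue, motivation, reward)."""
    n_hidden = params.w_rec.shape[0]
    hidden = np.empty((N_STEPS, n_hidden))
    h = np.zeros(n_hidden)
    for t in range(N_STEPS):
        x = np.array([trial.cue[t], trial.motivation[t], trial.reward[t]])
        h = _sigmoid(params.w_in @ x + params.w_rec @ h)
        hidden[t] = h
    return RNNTrace(hidden, hidden @ params.w_out)


def default_rnn_schedule(n_batches: int = 300_000, gamma: float = 0.9) -> TrainSchedule:
    """Learning rate 1e-2 → 1e-4 geometric per batch, γ = 0.9."""
    return TrainSchedule(1e-2, 1e-4, n_batches, gamma)


def train_rnn(
    schedule: TrainSchedule | None = None,
    rng: np.random.Generator | None = None,
    batch_size: int = 20,
    motivation_blind: bool = False,
    full_bptt: bool = True,
    loss_every: int = 100,
):
    """Train the value RNN by TD(0) on batches of random trials.

    Per batch, ``batch_size`` trial types are drawn uniformly from the six;
    TD errors δ_t = r_t + γ·v_{t+1} − v_t (v beyond the trial is 0) are
    backpropagated semi-gradient style through ``w_rec`` and ``w_out``
    only, through the full within-trial history (``full_bptt=False``
    restricts credit to the previous step's activations; that variant
    cannot carry the cue across the delay and is kept for comparison).
    Gradients are averaged over the batch and applied once per batch.

    Returns ``(params, loss_history)`` where the loss is the batch mean
    squared TD error sampled every ``loss_every`` batches.

    Raises ``RuntimeError`` if the loss diverges.
    """
    if rng is None:
        rng = np.random.default_rng()
    if schedule is None:
        schedule = default_rnn_schedule()
    params = init_rnn(rng)
    n_hidden = params.w_rec.shape[0]
    gamma = schedule.gamma
    trials = [make_trial(s) for s in TRIAL_TYPES]
    cues = np.stack([tr.cue for tr in trials])  # (6, 20)
    movs = np.stack(
        [np.zeros(N_STEPS) if motivation_blind else tr.motivation for tr in trials]
    )
    rews = np.stack([tr.reward for tr in trials])
    losses = []
    # divergence is detected explicitly in the loop; the float overflow en
    # route to the RuntimeError is expected, not a numerical accident
    with np.errstate(over="ignore", invalid="ignore"):
        return _train_rnn_loop(
            params, schedule, rng, batch_size, full_bptt, loss_every,
            cues, movs, rews, losses,
        )


def _train_rnn_loop(
    params, schedule, rng, batch_size, full_bptt, loss_every, cues, movs, rews, losses
):
    n_hidden = params.w_rec.shape[0]
    gamma = schedule.gamma
    for b in range(schedule.n_steps):
        lr = schedule.lr(b)
        kinds = rng.integers(len(TRIAL_TYPES), size=batch_size)
        R = rews[kinds]  # (B, 20)
        X = np.stack([cues[kinds], movs[kinds], R], axis=2)  # (B, 20, 3)
        H = np.empty((N_STEPS, batch_size, n_hidden))
        h = np.zeros((batch_size, n_hidden))
        for t in range(N_STEPS):
            h = _sigmoid(X[:, t, :] @ params.w_in.T + h @ params.w_rec.T)
            H[t] = h
        V = H @ params.w_out  # (20, B)
        delta = R.T + gamma * np.vstack([V[1:], np.zeros((1, batch_size))]) - V

        dw_out = np.zeros(n_hidden)
        dw_rec = np.zeros((n_hidden, n_hidden))
        if not full_bptt:
            for t in range(N_STEPS):
                dw_out += delta[t] @ H[t]
                gz = (delta[t][:, None] * params.w_out) * H[t] * (1.0 - H[t])
                h_prev = H[t - 1] if t > 0 else np.zeros((batch_size, n_hidden))
                dw_rec += gz.T @ h_prev
        else:
            gh = np.zeros((batch_size, n_hidden))
            for t in range(N_STEPS - 1, -1, -1):
                dw_out += delta[t] @ H[t]
                gh = gh + delta[t][:, None] * params.w_out
                gz = gh * H[t] * (1.0 - H[t])
                h_prev = H[t - 1] if t > 0 else np.zeros((batch_size, n_hidden))
                dw_rec += gz.T @ h_prev
                gh = gz @ params.w_rec
        params.w_out += lr * dw_out / batch_size
        params.w_rec += lr * dw_rec / batch_size

        if b % loss_every == 0:
            loss = float(np.mean(delta**2))
            losses.append(loss)
            if not np.isfinite(loss) or loss > 1e3:
                raise RuntimeError(
                    f"TD training diverged at batch {b}: mean squared TD error {loss}"
                )
    return params, np.array(losses)


def trial_mse(
    params: RNNParams, gamma: float = 0.9, oracle=expected_value_trace
) -> float:
    """Mean squared error between the network's value traces and the oracle
    traces, pooled over all six trial types and all 20 steps."""
    errs = []
    for spec in TRIAL_TYPES:
        trace = rnn_forward(params, make_trial(spec))
        errs.append((trace.v - oracle(spec, gamma)) ** 2)
    return float(np.mean(errs))
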