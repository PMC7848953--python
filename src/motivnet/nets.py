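"""Shared machinery for motivation-aware temporal-difference learning.

Small feedforward networks approximate Q-functions whose inputs include the
agent's motivation vector alongside its state.  Learning is semi-gradient
TD(0): the scalar TD error is backpropagated only through the output unit of
the selected action, with the error held constant in the gradient.

Everything here is deliberately minimal — plain numpy arrays, no autograd —
because the networks are tiny (a few hundred units) and the per-step update
touches only the selected output head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg.blas import dger

__all__ = [
    "Layer",
    "MLPParams",
    "PolicySpec",
    "TrainSchedule",
    "init_mlp",
    "forward",
    "td_error",
    "backprop_vectors",
    "selected_gradient",
    "add_scaled_",
    "GradAccumulator",
    "update_selected",
    "select_action",
    "anneal",
    "save_params",
    "load_params",
]

ACTIVATIONS = ("sigmoid", "leaky_relu", "linear")


@dataclass
class Layer:
    """One affine layer: ``a = act(W x + b)``. W has shape (n_out, n_in)."""

    W: np.ndarray
    b: np.ndarray
    activation: str
    alpha: float = 0.0  # leak slope, used only by leaky_relu

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ValueError("layer weight/bias shapes inconsistent")


@dataclass
class MLPParams:
    """An ordered stack of layers plus a free-form input spec.

    ``input_spec`` records the input dimensionality and any normalization
    constants the environment encoder uses, so that serialized parameters are
    self-describing.
    """

    layers: list[Layer]
    input_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers[:-1], self.layers[1:]):
            if hi.W.shape[1] != lo.W.shape[0]:
                raise ValueError(
                    f"layer shapes do not chain: {lo.W.shape} -> {hi.W.shape}"
                )

    @property
    def n_inputs(self) -> int:
        return self.layers[0].W.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.layers[-1].W.shape[0]

    def copy(self) -> "MLPParams":
        return MLPParams(
            [Layer(l.W.copy(), l.b.copy(), l.activation, l.alpha) for l in self.layers],
            dict(self.input_spec),
        )


@dataclass
class PolicySpec:
    """Action-selection rule: epsilon-greedy, softmax(beta) or deterministic."""

    kind: str
    epsilon: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "epsilon_greedy":
            if self.epsilon is None or not 0.0 <= self.epsilon <= 1.0:
                raise ValueError("epsilon_greedy needs epsilon in [0, 1]")
        elif self.kind == "softmax":
            if self.beta is None or self.beta <= 0:
                raise ValueError("softmax needs beta > 0")
        elif self.kind != "deterministic":
            raise ValueError(f"unknown policy kind {self.kind!r}")


@dataclass
class TrainSchedule:
    """Geometric learning-rate / exploration schedule and the discount.

    Both the learning rate and (when given) epsilon decay geometrically in the
    step index, from their start to their end value over ``n_steps``.
    """

    lr_start: float
    lr_end: float
    n_steps: int
    gamma: float
    eps_start: float | None = None
    eps_end: float | None = None

    def __post_init__(self) -> None:
        if not (self.lr_start >= self.lr_end > 0):
            raise ValueError("need lr_start >= lr_end > 0")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if (self.eps_start is None) != (self.eps_end is None):
            raise ValueError("give both or neither of eps_start/eps_end")
        for e in (self.eps_start, self.eps_end):
            if e is not None and not 0.0 <= e <= 1.0:
                raise ValueError("epsilon endpoints must lie in [0, 1]")

    def lr(self, t: int) -> float:
        return anneal(self.lr_start, self.lr_end, t, self.n_steps)

    def eps(self, t: int) -> float:
        if self.eps_start is None:
            raise ValueError("schedule has no epsilon endpoints")
        return anneal(self.eps_start, self.eps_end, t, self.n_steps)


def init_mlp(
    layer_sizes,
    activations,
    init_rule="xavier",
    rng: np.random.Generator | None = None,
    alpha: float = 0.2,
    gain=1.0,
) -> MLPParams:
    """Initialize a feedforward stack.

    Parameters
    ----------
    layer_sizes : sequence of int
        ``[n_in, h1, ..., n_out]``; must contain at least two entries.
    activations : str or sequence of str
        Activation per layer (a single string is broadcast to all layers).
    init_rule : ``"xavier"`` or ``("uniform", lo, hi)``
        Xavier draws are uniform on ±sqrt(6 / (fan_in + fan_out)), which has
        variance 2 / (fan_in + fan_out).  Biases start at zero.
    alpha : float
        Leak slope recorded on every leaky_relu layer.
    gain : float or sequence of float
        Multiplier on the Xavier scale, per layer.  Stacked logistic-sigmoid
        layers attenuate signal variance by σ'(0)² = 1/16 per layer, so deep
        sigmoid trunks use gain 4 to keep activations from collapsing toward
        the constant 0.5.
    """
    if len(layer_sizes) < 2:
        raise ValueError("need at least an input and an output size")
    if rng is None:
        rng = np.random.default_rng()
    n_layers = len(layer_sizes) - 1
    if isinstance(activations, str):
        activations = [activations] * n_layers
    if len(activations) != n_layers:
        raise ValueError("one activation per layer required")
    if np.isscalar(gain):
        gain = [float(gain)] * n_layers
    if len(gain) != n_layers:
        raise ValueError("one gain per layer required")

    layers = []
    for n_in, n_out, act, g in zip(layer_sizes[:-1], layer_sizes[1:], activations, gain):
        if init_rule == "xavier":
            lim = g * np.sqrt(6.0 / (n_in + n_out))
            W = rng.uniform(-lim, lim, size=(n_out, n_in))
        elif isinstance(init_rule, (tuple, list)) and init_rule[0] == "uniform":
            lo, hi = init_rule[1], init_rule[2]
            W = rng.uniform(lo, hi, size=(n_out, n_in))
        else:
            raise ValueError(f"unknown init rule {init_rule!r}")
        layers.append(
            Layer(W, np.zeros(n_out), act, alpha if act == "leaky_relu" else 0.0)
        )
    return MLPParams(layers)


def _apply_activation(z: np.ndarray, layer: Layer) -> np.ndarray:
    if layer.activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if layer.activation == "leaky_relu":
        return np.where(z > 0, z, layer.alpha * z)
    return z


def _activation_deriv(z: np.ndarray, a: np.ndarray, layer: Layer) -> np.ndarray:
    if layer.activation == "sigmoid":
        return a * (1.0 - a)
    if layer.activation == "leaky_relu":
        return np.where(z > 0, 1.0, layer.alpha)
    return np.ones_like(z)


def forward(params: MLPParams, x: np.ndarray):
    """Run the network on one input vector.

    Returns ``(cache, output)``.  The cache holds the input, per-layer
    pre-activations and activations — enough to backpropagate later ("the
    activations corresponding to the previous step" in TD updates).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_inputs,):
        raise ValueError(f"input shape {x.shape} != ({params.n_inputs},)")
    activations = [x]
    zs = []
    a = x
    for layer in params.layers:
        z = layer.W @ a + layer.b
        a = _apply_activation(z, layer)
        zs.append(z)
        activations.append(a)
    return {"activations": activations, "zs": zs}, a


def td_error(r: float, gamma: float, q_next_best: float, q_selected: float) -> float:
    """One-step TD error: δ = r + γ·max_a' Q(s', a') − Q(s, a).

    Pass ``q_next_best = 0`` for terminal transitions.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    return r + gamma * q_next_best - q_selected


def backprop_vectors(params: MLPParams, cache: dict, selected: int):
    """Per-layer pre-activation sensitivities of the selected output.

    Returns ``[g_0, ..., g_L]`` with ``∂out[selected]/∂W_l = outer(g_l, a_l)``
    and ``∂out[selected]/∂b_l = g_l``.  The output layer's vector has a
    single nonzero entry, so non-selected output rows get zero gradient.
    """
    n_out = params.n_outputs
    if not 0 <= selected < n_out:
        raise IndexError(f"selected output {selected} out of range 0..{n_out - 1}")
    activations, zs = cache["activations"], cache["zs"]
    gs = [None] * len(params.layers)
    top = params.layers[-1]
    g = np.zeros(n_out)
    g[selected] = _activation_deriv(
        zs[-1][selected : selected + 1], activations[-1][selected : selected + 1], top
    )[0]
    for li in range(len(params.layers) - 1, -1, -1):
        gs[li] = g
        if li > 0:
            layer = params.layers[li]
            below = params.layers[li - 1]
            g = (layer.W.T @ g) * _activation_deriv(zs[li - 1], activations[li], below)
    return gs


def selected_gradient(params: MLPParams, cache: dict, selected: int):
    """Materialized gradient of the selected output's value, one
    ``(dW, db)`` pair per layer."""
    gs = backprop_vectors(params, cache, selected)
    activations = cache["activations"]
    return [(np.outer(g, a), g) for g, a in zip(gs, activations)]


def add_scaled_(params: MLPParams, grads, coef: float) -> MLPParams:
    """In-place ``params += coef * grads`` (grads as from selected_gradient)."""
    for layer, (gW, gb) in zip(params.layers, grads):
        layer.W += coef * gW
        layer.b += coef * gb
    return params


def _rank1_update_(W: np.ndarray, g: np.ndarray, a: np.ndarray, coef: float) -> None:
    """In-place ``W += coef * outer(g, a)`` without temporaries (BLAS ger on
    the transposed, Fortran-ordered view)."""
    dger(coef, a, g, a=W.T, overwrite_a=1)


def update_selected(
    params: MLPParams, cache: dict, selected: int, delta: float, lr: float
) -> MLPParams:
    """Semi-gradient TD update through the selected output head (in place).

    The step is ``w += lr · δ · ∂Q_selected/∂w`` with δ treated as a constant
    — a gradient step on the squared TD error in the semi-gradient sense.
    """
    if delta == 0.0:
        # still validate the index
        if not 0 <= selected < params.n_outputs:
            raise IndexError("selected output out of range")
        return params
    gs = backprop_vectors(params, cache, selected)
    coef = lr * delta
    activations = cache["activations"]
    for layer, g, a in zip(params.layers, gs, activations):
        _rank1_update_(layer.W, g, a, coef)
        layer.b += coef * g
    return params


class GradAccumulator:
    """Accumulates selected-output semi-gradients for minibatched updates."""

    def __init__(self, params: MLPParams):
        self.dW = [np.zeros_like(l.W) for l in params.layers]
        self.db = [np.zeros_like(l.b) for l in params.layers]
        self.count = 0

    def add(self, params: MLPParams, cache: dict, selected: int, delta: float) -> None:
        gs = backprop_vectors(params, cache, selected)
        for dW, db, g, a in zip(self.dW, self.db, gs, cache["activations"]):
            _rank1_update_(dW, g, a, delta)
            db += delta * g
        self.count += 1

    def apply_(self, params: MLPParams, lr: float, average: bool = True) -> None:
        """Apply the accumulated gradient (mean by default, or summed as if
        the constituent steps had been taken individually), then reset."""
        if self.count == 0:
            return
        coef = lr / self.count if average else lr
        for layer, dW, db in zip(params.layers, self.dW, self.db):
            layer.W += coef * dW
            layer.b += coef * db
            dW[:] = 0.0
            db[:] = 0.0
        self.count = 0


def select_action(
    q_values: np.ndarray,
    policy: PolicySpec,
    available_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Pick an action index under the policy, restricted to available actions.

    Masked-out actions are never chosen.  ``epsilon_greedy`` takes the argmax
    with probability 1−ε and otherwise a uniform available action; ``softmax``
    samples with probability ∝ exp(β·Q) over available actions.
    """
    q_values = np.asarray(q_values, dtype=float)
    if available_mask is None:
        available = np.arange(q_values.size)
    else:
        available = np.flatnonzero(np.asarray(available_mask, dtype=bool))
    if available.size == 0:
        raise ValueError("no available actions")
    if rng is None:
        rng = np.random.default_rng()

    q_avail = q_values[available]
    if policy.kind == "deterministic":
        return int(available[int(np.argmax(q_avail))])
    if policy.kind == "epsilon_greedy":
        if policy.epsilon > 0 and rng.random() < policy.epsilon:
            return int(rng.choice(available))
        return int(available[int(np.argmax(q_avail))])
    # softmax
    logits = policy.beta * q_avail
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return int(available[int(rng.choice(p.size, p=p))])


def anneal(start: float, end: float, t: float, T: float) -> float:
    """Geometric interpolation ``start · (end/start)^(t/T)``."""
    if start <= 0 or end <= 0:
        raise ValueError("geometric annealing needs positive endpoints")
    if T <= 0:
        raise ValueError("T must be positive")
    return float(start * (end / start) ** (t / T))


# ---------------------------------------------------------------------------
# serialization: one named array per layer weight/bias in a compressed
# container, plus a JSON sidecar with the layer specs and input spec.

def save_params(params: MLPParams, path) -> None:
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(params.layers):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    np.savez_compressed(path, **arrays)
    from . import __version__

    sidecar = {
        "motivnet_version": __version__,
        "n_layers": len(params.layers),
        "activations": [l.activation for l in params.layers],
        "alphas": [l.alpha for l in params.layers],
        "input_spec": _jsonable(params.input_spec),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_params(path) -> MLPParams:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    data = np.load(path)
    layers = [
        Layer(
            data[f"W{i}"],
            data[f"b{i}"],
            sidecar["activations"][i],
            sidecar["alphas"][i],
        )
        for i in range(sidecar["n_layers"])
    ]
    return MLPParams(layers, sidecar["input_spec"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
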