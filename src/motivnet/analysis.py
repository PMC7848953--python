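"""Population analysis of value-network units.

Mirrors the analysis applied to ventral pallidum recordings: units are
clustered by their activity in the strong-reward and strong-punishment
trials (z-score → 3 PCA components → complete-linkage hierarchical
clustering), compared against a clustering implied by their recurrent
connectivity, and summarized as a push-pull circuit: mean recurrent weight
within each valence cluster versus between the two clusters.

The expectation for a trained value RNN is two oppositely tuned clusters
(reward-preferring and punishment-preferring units) with net excitation
within a cluster and net inhibition between clusters — the classic
push-pull motif that maintains reward expectation across the cue-outcome
delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .pavlovian import RNNParams, TrialSpec, make_trial, rnn_forward

__all__ = [
    "ClusterAssignment",
    "ConnectivitySummary",
    "activity_from_rnn",
    "cluster_units",
    "valence_clusters",
    "cluster_valence_difference",
    "weight_embedding",
    "push_pull_summary",
]


@dataclass
class ClusterAssignment:
    """Per-unit cluster labels (contiguous from 0) and the merge tree."""

    labels: np.ndarray
    linkage: np.ndarray
    n_clusters: int
    kept: np.ndarray  # indices of units that entered the clustering


@dataclass
class ConnectivitySummary:
    """Mean ± SEM of recurrent weights within and between the two valence
    clusters (self-connections excluded)."""

    mean_within: float
    sem_within: float
    mean_between: float
    sem_between: float


def activity_from_rnn(params: RNNParams) -> np.ndarray:
    """Unit activity tensor (units × timesteps × 2 conditions) from the
    strong-reward and strong-punishment trials."""
    traces = [
        rnn_forward(params, make_trial(TrialSpec(v, 1.0))).hidden.T for v in (1, -1)
    ]
    return np.stack(traces, axis=2)


def cluster_units(activity: np.ndarray, n_clusters: int = 3) -> ClusterAssignment:
    """Cluster units by activity: per-unit z-score across the concatenated
    condition traces, first three PCA components, then agglomerative
    hierarchical clustering (Euclidean distance, complete linkage).

    Constant-rate units (zero variance) are excluded with a warning and
    keep no label (their entries in ``labels`` are −1).
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim == 3:
        flat = activity.reshape(activity.shape[0], -1)
    else:
        flat = activity
    n_units = flat.shape[0]
    if n_units < 2:
        raise ValueError("need at least two units")
    std = flat.std(axis=1)
    kept = np.flatnonzero(std > 0)
    if kept.size < n_units:
        warnings.warn(
            f"excluding {n_units - kept.size} constant-rate unit(s) from clustering"
        )
    if kept.size < n_clusters:
        raise ValueError("fewer varying units than requested clusters")
    z = (flat[kept] - flat[kept].mean(axis=1, keepdims=True)) / std[kept, None]
    n_comp = min(3, z.shape[1], kept.size)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(z)
    tree = linkage(pcs, method="complete", metric="euclidean")
    raw = fcluster(tree, t=n_clusters, criterion="maxclust")
    labels = np.full(n_units, -1, dtype=int)
    # relabel contiguously from 0 in order of first appearance
    remap = {}
    for unit, lab in zip(kept, raw):
        labels[unit] = remap.setdefault(lab, len(remap))
    return ClusterAssignment(labels, tree, n_clusters, kept)


def valence_clusters(assignment: ClusterAssignment) -> tuple:
    """Indices of the two largest clusters (the putative positive- and
    negative-valence populations)."""
    labs, counts = np.unique(
        assignment.labels[assignment.labels >= 0], return_counts=True
    )
    if labs.size < 2:
        raise ValueError("need at least two clusters")
    order = labs[np.argsort(counts)[::-1]]
    a, b = order[0], order[1]
    return (
        np.flatnonzero(assignment.labels == a),
        np.flatnonzero(assignment.labels == b),
    )


def cluster_valence_difference(activity: np.ndarray, units) -> float:
    """Mean activity difference (strong reward − strong punishment) of a
    unit group; opposite signs for the two valence clusters."""
    activity = np.asarray(activity, dtype=float)
    return float(
        activity[units, :, 0].mean() - activity[units, :, 1].mean()
    )


def weight_embedding(
    params: RNNParams,
    perplexity: float = 30.0,
    rng: np.random.Generator | None = None,
    direction: str = "outgoing",
):
    """Weight-based unit similarity: correlation matrix of the units'
    recurrent weight vectors, plus a 2-D t-SNE embedding for display.

    ``direction="outgoing"`` uses each unit's postsynaptic (outgoing) weight
    vector — column j of W, since h_t = σ(W h_{t−1}) makes W[i, j] the
    weight from unit j onto unit i; ``"incoming"`` uses the rows instead.
    Returns ``(coords, corr)``.  The embedding is visualization-only.
    """
    w = np.asarray(params.w_rec, dtype=float)
    n = w.shape[0]
    if n < 3:
        raise ValueError("need at least three units to embed")
    vectors = w.T if direction == "outgoing" else w
    corr = np.corrcoef(vectors)
    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    dist = np.sqrt(np.maximum(0.0, 2.0 * (1.0 - corr)))
    tsne = TSNE(
        n_components=2,
        perplexity=min(perplexity, n - 1),
        metric="precomputed",
        init="random",
        random_state=seed,
    )
    coords = tsne.fit_transform(dist)
    return coords, corr


def plot_population(params: RNNParams, path, n_clusters: int = 3,
                    rng: np.random.Generator | None = None) -> None:
    """Write a summary figure: cluster-mean activity traces for the two
    valence clusters, the recurrent weight matrix ordered by cluster, and
    the weight-based t-SNE embedding colored by activity cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    act = activity_from_rnn(params)
    assignment = cluster_units(act, n_clusters)
    ga, gb = valence_clusters(assignment)
    coords, _ = weight_embedding(params, rng=rng)

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for g, color, name in [(ga, "tab:red", "cluster A"), (gb, "tab:blue", "cluster B")]:
        for cond, style, lbl in [(0, "-", "reward"), (1, "--", "punishment")]:
            axes[0].plot(act[g, :, cond].mean(axis=0), style, color=color,
                         label=f"{name}, strong {lbl}")
    axes[0].set_xlabel("trial step")
    axes[0].set_ylabel("mean unit activity")
    axes[0].legend(fontsize=6)

    order = np.concatenate([ga, gb])
    im = axes[1].imshow(params.w_rec[np.ix_(order, order)], cmap="coolwarm")
    axes[1].set_title("recurrent weights (cluster-ordered)", fontsize=8)
    fig.colorbar(im, ax=axes[1], shrink=0.8)

    colors = np.full(params.w_rec.shape[0], "tab:green", dtype=object)
    colors[ga] = "tab:red"
    colors[gb] = "tab:blue"
    axes[2].scatter(coords[:, 0], coords[:, 1], c=list(colors), s=18)
    axes[2].set_title("weight-based embedding", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__.append("plot_population")


def push_pull_summary(w_rec: np.ndarray, labels) -> ConnectivitySummary:
    """Mean ± SEM of recurrent weights within and between two unit groups.

    ``labels`` is a pair of index arrays (the two valence clusters).  The
    diagonal (self-weights) is excluded from the within pools.
    """
    w = np.asarray(w_rec, dtype=float)
    ga, gb = (np.asarray(g, dtype=int) for g in labels)
    if ga.size < 2 or gb.size < 2:
        raise ValueError("each cluster needs at least two units")
    within = []
    for g in (ga, gb):
        block = w[np.ix_(g, g)]
        off = ~np.eye(g.size, dtype=bool)
        within.append(block[off])
    within = np.concatenate(within)
    between = np.concatenate([w[np.ix_(ga, gb)].ravel(), w[np.ix_(gb, ga)].ravel()])
    return ConnectivitySummary(
        float(within.mean()),
        float(within.std(ddof=1) / np.sqrt(within.size)),
        float(between.mean()),
        float(between.std(ddof=1) / np.sqrt(between.size)),
    )
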