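"""k-means partitioning of a network via its adjacency matrix.

Each node is represented by its adjacency-matrix row (binary by default,
confidence-weighted behind a flag) and clustered with Lloyd's algorithm in
Euclidean space. The cluster count follows the rule of thumb
k = round(sqrt(n/2)) when not specified.

The Lloyd loop is implemented here rather than delegated so that the run
exposes a per-iteration inertia trace and a documented empty-cluster policy
(re-seed at the point farthest from its current centroid); scikit-learn's
KMeans is used in the test suite as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import InteractionNetwork

__all__ = [
    "cluster_count_rule",
    "ClusterAssignment",
    "kmeans_partition",
    "GraphKMeans",
    "ClusterResults",
]


def cluster_count_rule(n: int) -> int:
    """Rule-of-thumb cluster count k = round(sqrt(n/2)), at least 1.

    For the canonical 201-node interactome this gives round(sqrt(100.5)) = 10.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(1, round(math.sqrt(n / 2)))


@dataclass(frozen=True)
class ClusterAssignment:
    """Node -> cluster-id partition (ids 1..k) for a given k and seed."""

    labels: dict[str, int]
    k: int
    seed: int
    inertia: float
    inertia_history: tuple[float, ...]  # best restart, one value per Lloyd iteration
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.labels)
        return pd.DataFrame(
            {"cluster": [self.labels[n] for n in nodes]},
            index=pd.Index(nodes, name="node"),
        )


def adjacency_features(
    net: InteractionNetwork, *, use_confidence_weights: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Adjacency-matrix rows as the node feature space (lexicographic order)."""
    nodes = net.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    X = np.zeros((len(nodes), len(nodes)))
    for a, b, c in net.edges():
        w = c if use_confidence_weights else 1.0
        X[idx[a], idx[b]] = w
        X[idx[b], idx[a]] = w
    return X, nodes


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, float, list[float]]:
    """One seeded Lloyd run; returns labels, inertia, per-iteration inertia."""
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # empty-cluster safeguard: re-seed at the point farthest from its centroid
        for c in range(k):
            if not (new_labels == c).any():
                farthest = d2[np.arange(n), new_labels].argmax()
                new_labels[farthest] = c
        inertia = float(((X - centroids[new_labels]) ** 2).sum())
        history.append(inertia)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = X[labels == c].mean(axis=0)
    # final inertia against the updated centroids
    final = float(((X - centroids[labels]) ** 2).sum())
    history.append(final)
    return labels, final, history


def kmeans_partition(
    net: InteractionNetwork,
    k: int,
    seed: int = 0,
    *,
    use_confidence_weights: bool = False,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Partition nodes into k clusters by k-means on adjacency rows.

    ``n_init`` random restarts are run from the seeded generator and the
    lowest-inertia solution kept; identical seeds give identical labels.
    """
    if not 1 <= k <= net.n_nodes:
        raise ValueError(f"k must be in [1, {net.n_nodes}], got {k}")
    X, nodes = adjacency_features(net, use_confidence_weights=use_confidence_weights)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for _ in range(n_init):
        labels, inertia, history = _lloyd(X, k, rng, max_iter)
        if best is None or inertia < best[1]:
            best = (labels, inertia, history)
    labels, inertia, history = best
    return ClusterAssignment(
        labels={n: int(lab) + 1 for n, lab in zip(nodes, labels)},
        k=k,
        seed=seed,
        inertia=inertia,
        inertia_history=tuple(history),
        n_iter=len(history),
    )


class GraphKMeans:
    """k-means clustering model over a network's adjacency matrix.

    ``k=None`` applies the sqrt(n/2) rule of thumb at fit time.
    """

    def __init__(
        self,
        net: InteractionNetwork,
        k: int | None = None,
        *,
        seed: int = 0,
        use_confidence_weights: bool = False,
        n_init: int = 10,
        max_iter: int = 300,
    ):
        self.net = net
        self.k = k if k is not None else cluster_count_rule(net.n_nodes)
        self.seed = seed
        self.use_confidence_weights = use_confidence_weights
        self.n_init = n_init
        self.max_iter = max_iter

    def fit(self) -> "ClusterResults":
        assignment = kmeans_partition(
            self.net,
            self.k,
            self.seed,
            use_confidence_weights=self.use_confidence_weights,
            n_init=self.n_init,
            max_iter=self.max_iter,
        )
        return ClusterResults(self, assignment)


class ClusterResults:
    """Fitted partition with its inertia diagnostics."""

    def __init__(self, model: GraphKMeans, assignment: ClusterAssignment):
        self.model = model
        self.assignment = assignment

    @property
    def labels(self) -> dict[str, int]:
        return self.assignment.labels

    @property
    def inertia(self) -> float:
        return self.assignment.inertia

    def to_frame(self) -> pd.DataFrame:
        return self.assignment.to_frame()

    def summary(self) -> str:
        sizes = pd.Series(list(self.labels.values())).value_counts().sort_index()
        lines = [
            "Graph k-means summary",
            "=====================",
            f"k (clusters)    {self.assignment.k}",
            f"seed            {self.assignment.seed}",
            f"inertia         {self.assignment.inertia:.4f}",
            f"Lloyd sweeps    {self.assignment.n_iter}",
            "cluster sizes   " + ", ".join(f"{c}:{s}" for c, s in sizes.items()),
        ]
        return "\n".join(lines)
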