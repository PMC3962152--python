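"""Topological characterization of an interaction network.

Degree distribution with a scale-free power-law fit, average clustering
coefficient, characteristic path length and diameter, and per-node
degree/betweenness centralities. The power-law exponent is estimated by
ordinary least squares on the log10-log10 degree-probability relation over
the raw (unbinned) distribution — the NetworkAnalyzer convention, under which
exponents below 1 can legitimately be reported even though a pure power law
with such an exponent is not normalizable on infinite support.

The statsmodels-style entry point is :class:`NetworkTopology`; ``fit()``
returns a :class:`TopologyResults` carrying the summary numbers and the
per-node centrality table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import InteractionNetwork, largest_component

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "TopologySummary",
    "degree_distribution",
    "fit_power_law",
    "average_clustering",
    "path_metrics",
    "betweenness",
    "centrality_table",
    "NetworkTopology",
    "TopologyResults",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Empirical distribution P(k) = (#nodes of degree k) / n.

    ``support`` lists every observed degree (including 0 if isolated nodes
    are present, so the probabilities sum to 1); the power-law fit uses only
    k >= 1.
    """

    support: tuple[int, ...]
    probability: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.probability.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, expected 1")

    @property
    def fit_support(self) -> tuple[int, ...]:
        """Degrees usable for the log-log fit (k >= 1)."""
        return tuple(k for k in self.support if k >= 1)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10 P(k) on log10 k: P(k) ~ k^(-gamma)."""

    gamma: float
    log_prefactor: float
    r_squared: float

    def predict(self, k: np.ndarray) -> np.ndarray:
        """Fitted P(k) on the original scale."""
        return 10.0 ** (self.log_prefactor - self.gamma * np.log10(np.asarray(k)))


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    fit: PowerLawFit
    avg_clustering: float
    avg_clustering_min_degree2: float
    char_path_length: float
    diameter: int


def degree_distribution(net: InteractionNetwork) -> DegreeDistribution:
    """Empirical degree distribution of the network."""
    if net.n_nodes == 0:
        raise ValueError("degree distribution undefined for an empty network")
    degrees = [d for _, d in net.graph.degree()]
    n = len(degrees)
    counts: dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    support = tuple(sorted(counts))
    prob = {k: counts[k] / n for k in support}
    return DegreeDistribution(support=support, probability=prob)


def fit_power_law(
    dist: DegreeDistribution, *, log_binning: bool = False, n_bins: int = 10
) -> PowerLawFit:
    """Least-squares power-law fit of the degree distribution.

    Regresses log10 P(k) on log10 k over the raw support (k >= 1) and returns
    gamma = -slope together with the regression R². ``log_binning`` pools the
    probability mass into logarithmically spaced degree bins first, which
    de-noises the sparse tail at the cost of resolution.
    """
    ks = np.array(dist.fit_support, dtype=float)
    ps = np.array([dist.probability[int(k)] for k in ks])
    if log_binning and ks.size >= 2:
        edges = np.logspace(np.log10(ks.min()), np.log10(ks.max() + 1), n_bins + 1)
        idx = np.clip(np.digitize(ks, edges) - 1, 0, n_bins - 1)
        binned_k, binned_p = [], []
        for b in range(n_bins):
            mask = idx == b
            if mask.any():
                # geometric-mean degree, density = mass / bin width
                binned_k.append(np.exp(np.mean(np.log(ks[mask]))))
                binned_p.append(ps[mask].sum() / (edges[b + 1] - edges[b]))
        ks, ps = np.array(binned_k), np.array(binned_p)
    if len(np.unique(ks)) < 2:
        raise ValueError("power-law fit needs >=2 distinct degrees with k >= 1")
    x, y = np.log10(ks), np.log10(ps)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(gamma=-slope, log_prefactor=float(intercept), r_squared=r2)


def average_clustering(net: InteractionNetwork, *, count_low_degree: bool = True) -> float:
    """Network clustering coefficient: mean local coefficient over nodes.

    Local coefficient of v is 2·t(v)/(deg(v)·(deg(v)−1)), t(v) the number of
    edges among v's neighbours. Nodes of degree < 2 contribute 0 by default;
    ``count_low_degree=False`` excludes them from the mean instead (both
    conventions appear in network-analysis software).
    """
    if net.n_nodes == 0:
        raise ValueError("clustering undefined for an empty network")
    if count_low_degree:
        return nx.average_clustering(net.graph, count_zeros=True)
    eligible = [n for n in net.graph if net.graph.degree(n) >= 2]
    if not eligible:
        return 0.0
    return nx.average_clustering(net.graph, nodes=eligible, count_zeros=True)


def path_metrics(net: InteractionNetwork) -> tuple[float, int]:
    """Characteristic path length and diameter of the largest component.

    The characteristic path length is the mean shortest-path distance over
    unordered connected node pairs; the diameter is the maximum. A
    single-node component yields (0, 0) with a warning.
    """
    comp = largest_component(net)
    if comp.n_nodes == 1:
        warnings.warn("single-node component: path metrics are degenerate (0, 0)")
        return 0.0, 0
    g = comp.graph
    cpl = nx.average_shortest_path_length(g)
    diam = nx.diameter(g)
    return float(cpl), int(diam)


def betweenness(
    net: InteractionNetwork, *, use_confidence_weights: bool = False, normalized: bool = False
) -> dict[str, float]:
    """Shortest-path betweenness centrality (Brandes accumulation).

    Unnormalized by default: the value for v is the sum over ordered pairs
    s != t != v of sigma_st(v)/sigma_st, halved for undirected graphs. With
    ``use_confidence_weights`` shortest paths minimise total edge distance
    1/confidence, so high-confidence edges are preferred routes.
    """
    g = net.graph
    weight = None
    if use_confidence_weights:
        g = g.copy()
        for u, v, d in g.edges(data=True):
            d["distance"] = 1.0 / max(d["confidence"], 1e-12)
        weight = "distance"
    return nx.betweenness_centrality(g, normalized=normalized, weight=weight)


def centrality_table(
    net: InteractionNetwork, *, use_confidence_weights: bool = False
) -> pd.DataFrame:
    """Per-node degree and betweenness, indexed by symbol (lexicographic).

    With ``use_confidence_weights`` the degree column is the node strength
    (sum of incident confidences) and betweenness uses confidence-derived
    distances.
    """
    bw = betweenness(net, use_confidence_weights=use_confidence_weights)
    if use_confidence_weights:
        deg = dict(net.graph.degree(weight="confidence"))
    else:
        deg = dict(net.graph.degree())
    nodes = net.nodes
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [bw[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


class NetworkTopology:
    """Topology model of an interaction network.

    Parameters
    ----------
    net
        The (already confidence-filtered) interaction network.
    use_confidence_weights
        Use confidence-weighted centralities instead of unit edge weights.
    log_binning
        Fit the power law on logarithmically binned degrees.
    """

    def __init__(
        self,
        net: InteractionNetwork,
        *,
        use_confidence_weights: bool = False,
        log_binning: bool = False,
    ):
        if net.n_nodes == 0:
            raise ValueError("cannot characterize an empty network")
        self.net = net
        self.use_confidence_weights = use_confidence_weights
        self.log_binning = log_binning

    def fit(self) -> "TopologyResults":
        dist = degree_distribution(self.net)
        fit = fit_power_law(dist, log_binning=self.log_binning)
        cpl, diam = path_metrics(self.net)
        summary = TopologySummary(
            n_nodes=self.net.n_nodes,
            n_edges=self.net.n_edges,
            fit=fit,
            avg_clustering=average_clustering(self.net),
            avg_clustering_min_degree2=average_clustering(
                self.net, count_low_degree=False
            ),
            char_path_length=cpl,
            diameter=diam,
        )
        table = centrality_table(
            self.net, use_confidence_weights=self.use_confidence_weights
        )
        return TopologyResults(self, dist, summary, table)


class TopologyResults:
    """Fitted topology: summary statistics plus the per-node centrality table."""

    def __init__(
        self,
        model: NetworkTopology,
        dist: DegreeDistribution,
        summary_stats: TopologySummary,
        table: pd.DataFrame,
    ):
        self.model = model
        self.degree_dist = dist
        self.stats = summary_stats
        self.centrality = table

    @property
    def gamma(self) -> float:
        return self.stats.fit.gamma

    @property
    def r_squared(self) -> float:
        return self.stats.fit.r_squared

    def to_dict(self) -> dict:
        s = self.stats
        return {
            "n_nodes": s.n_nodes,
            "n_edges": s.n_edges,
            "gamma": s.fit.gamma,
            "r_squared": s.fit.r_squared,
            "avg_clustering": s.avg_clustering,
            "avg_clustering_min_degree2": s.avg_clustering_min_degree2,
            "char_path_length": s.char_path_length,
            "diameter": s.diameter,
        }

    def summary(self) -> str:
        s = self.stats
        lines = [
            "Network topology summary",
            "========================",
            f"nodes                    {s.n_nodes}",
            f"edges                    {s.n_edges}",
            f"degree exponent (gamma)  {s.fit.gamma:.3f}",
            f"fit R^2                  {s.fit.r_squared:.3f}",
            f"avg clustering coeff     {s.avg_clustering:.3f}",
            f"  (excluding deg<2)      {s.avg_clustering_min_degree2:.3f}",
            f"characteristic path len  {s.char_path_length:.3f}",
            f"diameter                 {s.diameter}",
        ]
        return "\n".join(lines)

    def plot_degree_distribution(self, ax=None):
        """Log-log degree distribution with the fitted power law overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = np.array(self.degree_dist.fit_support, dtype=float)
        ps = np.array([self.degree_dist.probability[int(k)] for k in ks])
        ax.loglog(ks, ps, "o", label="P(k)")
        ax.loglog(ks, self.stats.fit.predict(ks), "-", label=(
            f"k^(-{self.stats.fit.gamma:.2f}), R²={self.stats.fit.r_squared:.2f}"
        ))
        ax.set_xlabel("degree k")
        ax.set_ylabel("P(k)")
        ax.legend()
        return ax
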