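"""Hub prioritization: top-N nodes by degree and by betweenness, intersected.

A hub here is a node that appears in the top-N under *both* centrality
rankings; the intersection ("common hubs") is the gene list carried forward
to expression meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .network import InteractionNetwork
from .topology import centrality_table

__all__ = ["HubSelection", "rank_nodes", "select_hubs", "HubModel", "HubResults"]

_METHODS = ("degree", "betweenness")


def rank_nodes(table: pd.DataFrame, method: str) -> list[str]:
    """Nodes in descending order of the chosen centrality.

    Ties are broken lexicographically by symbol, so the ranking is fully
    deterministic.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown ranking method {method!r}; expected one of {_METHODS}")
    if table.empty:
        raise ValueError("empty centrality table")
    order = sorted(table.index, key=lambda n: (-table.at[n, method], n))
    return order


@dataclass(frozen=True)
class HubSelection:
    """Top-N rankings under degree and betweenness and their intersection."""

    top_by_degree: tuple[str, ...]
    top_by_betweenness: tuple[str, ...]
    common_hubs: tuple[str, ...]  # sorted lexicographically
    n_top: int

    def __post_init__(self) -> None:
        expected = tuple(
            sorted(set(self.top_by_degree) & set(self.top_by_betweenness))
        )
        if self.common_hubs != expected:
            raise ValueError("common_hubs is not the intersection of the two lists")


def select_hubs(
    net: InteractionNetwork,
    n_top: int = 50,
    *,
    use_confidence_weights: bool = False,
    table: pd.DataFrame | None = None,
) -> HubSelection:
    """Rank by degree and betweenness, truncate to ``n_top``, intersect.

    ``table`` lets a caller reuse an existing centrality table instead of
    recomputing betweenness.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if table is None:
        table = centrality_table(net, use_confidence_weights=use_confidence_weights)
    by_deg = rank_nodes(table, "degree")[:n_top]
    by_btw = rank_nodes(table, "betweenness")[:n_top]
    common = tuple(sorted(set(by_deg) & set(by_btw)))
    return HubSelection(
        top_by_degree=tuple(by_deg),
        top_by_betweenness=tuple(by_btw),
        common_hubs=common,
        n_top=n_top,
    )


class HubModel:
    """Hub-prioritization model over an interaction network.

    ``fit()`` computes one centrality table, both rankings (weighted and
    unweighted variants available), and the common-hub intersection.
    """

    def __init__(
        self,
        net: InteractionNetwork,
        n_top: int = 50,
        *,
        use_confidence_weights: bool = False,
    ):
        if n_top < 1:
            raise ValueError("n_top must be >= 1")
        self.net = net
        self.n_top = n_top
        self.use_confidence_weights = use_confidence_weights

    def fit(self) -> "HubResults":
        table = centrality_table(
            self.net, use_confidence_weights=self.use_confidence_weights
        )
        sel = select_hubs(self.net, self.n_top, table=table)
        return HubResults(self, table, sel)


class HubResults:
    """Centrality table annotated with top-list membership flags."""

    def __init__(self, model: HubModel, table: pd.DataFrame, selection: HubSelection):
        self.model = model
        self.selection = selection
        t = table.copy()
        t["in_degree_top"] = t.index.isin(selection.top_by_degree)
        t["in_betweenness_top"] = t.index.isin(selection.top_by_betweenness)
        t["is_common_hub"] = t.index.isin(selection.common_hubs)
        self.table = t

    @property
    def common_hubs(self) -> tuple[str, ...]:
        return self.selection.common_hubs

    def summary(self) -> str:
        sel = self.selection
        lines = [
            "Hub selection summary",
            "=====================",
            f"top-N cutoff             {sel.n_top}",
            f"top-by-degree size       {len(sel.top_by_degree)}",
            f"top-by-betweenness size  {len(sel.top_by_betweenness)}",
            f"common hubs              {len(sel.common_hubs)}",
            "",
            "common hub symbols:",
            ", ".join(sel.common_hubs) if sel.common_hubs else "(none)",
        ]
        return "\n".join(lines)
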