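"""Weighted interaction-network substrate.

Parses STRING-style edge lists into a cleaned undirected network whose edges
carry a confidence score in [0, 1], and provides the confidence filter and
largest-component extraction that every downstream stage builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "EdgeListDialect",
    "InteractionNetwork",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "filter_by_confidence",
    "largest_component",
]


class EdgeListParseError(ValueError):
    """Malformed edge-list row; message carries the 1-based line number."""


@dataclass(frozen=True)
class EdgeListDialect:
    """Conventions of a tab-separated edge-list export.

    ``score_scale`` is either ``"unit"`` (confidences already in [0, 1]) or
    ``"string"`` (STRING-export integers in [0, 1000], divided by 1000 on
    read). Lines starting with ``#`` are always skipped.
    """

    score_scale: str = "unit"
    delimiter: str = "\t"
    has_header: bool = True

    def __post_init__(self) -> None:
        if self.score_scale not in ("unit", "string"):
            raise ValueError(f"unknown score_scale: {self.score_scale!r}")

    def parse_score(self, token: str, lineno: int) -> float:
        try:
            value = float(token)
        except ValueError:
            raise EdgeListParseError(
                f"line {lineno}: score {token!r} is not a number"
            ) from None
        if self.score_scale == "string":
            if not value.is_integer() or not 0 <= value <= 1000:
                raise EdgeListParseError(
                    f"line {lineno}: string-style score must be an integer in "
                    f"[0, 1000], got {token!r}"
                )
            value /= 1000.0
        if not 0.0 <= value <= 1.0:
            raise EdgeListParseError(
                f"line {lineno}: confidence {value} outside [0, 1]"
            )
        return value


class InteractionNetwork:
    """Simple undirected graph of protein symbols with per-edge confidence.

    Invariants: no self-loops, each unordered pair at most once, every
    confidence in [0, 1]. Node iteration order is lexicographic, which makes
    every downstream ranking and tie-break deterministic.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph() if graph is None else graph
        self._validate()

    def _validate(self) -> None:
        for u, v, d in self._g.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            c = d.get("confidence", 1.0)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} on edge {u}-{v} outside [0, 1]")
        for n in self._g.nodes:
            if not isinstance(n, str) or not n:
                raise ValueError(f"node symbol must be a non-empty string, got {n!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        """Build from ``(a, b, confidence)`` triples.

        Self-loops are dropped; duplicate unordered pairs collapse keeping the
        maximum confidence (the most permissive choice under later filtering).
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, c in edges:
            if a == b:
                continue
            if g.has_edge(a, b):
                c = max(c, g[a][b]["confidence"])
            g.add_edge(a, b, confidence=float(c))
        return cls(g)

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (edges carry ``confidence``)."""
        return self._g

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges as ``(a, b, confidence)`` with a < b, sorted."""
        for a, b in sorted(tuple(sorted(e)) for e in self._g.edges):
            yield a, b, self._g[a][b]["confidence"]

    def confidence(self, a: str, b: str) -> float:
        return self._g[a][b]["confidence"]

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __repr__(self) -> str:
        return f"<InteractionNetwork: {self.n_nodes} nodes, {self.n_edges} edges>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and list(self.edges()) == list(
            other.edges()
        )

    # -- transformations ---------------------------------------------------

    def filter_by_confidence(
        self,
        threshold: float,
        *,
        strict: bool = True,
        keep_isolated: bool = False,
    ) -> "InteractionNetwork":
        return filter_by_confidence(
            self, threshold, strict=strict, keep_isolated=keep_isolated
        )

    def largest_component(self) -> "InteractionNetwork":
        return largest_component(self)


def read_edge_list(
    path: str | Path,
    dialect: EdgeListDialect | None = None,
) -> InteractionNetwork:
    """Read a TSV edge list (``protein_a  protein_b  combined_score``).

    Cleaning on read: self-loops dropped, duplicate unordered pairs collapsed
    keeping the maximum confidence. ``#``-prefixed lines are comments. Raises
    :class:`EdgeListParseError` naming the offending line.
    """
    dialect = dialect or EdgeListDialect()
    path = Path(path)
    triples: list[tuple[str, str, float]] = []
    with path.open() as fh:
        seen_data = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect.has_header and not seen_data:
                seen_data = True  # first non-comment row is the header
                continue
            parts = line.split(dialect.delimiter)
            if len(parts) < 3:
                raise EdgeListParseError(
                    f"line {lineno}: expected >=3 columns, got {len(parts)}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise EdgeListParseError(f"line {lineno}: empty protein symbol")
            triples.append((a, b, dialect.parse_score(parts[2].strip(), lineno)))
    return InteractionNetwork.from_edges(triples)


def write_edge_list(
    net: InteractionNetwork,
    path: str | Path,
    dialect: EdgeListDialect | None = None,
) -> None:
    """Write the network back in the same TSV dialect ``read_edge_list`` consumes."""
    dialect = dialect or EdgeListDialect()
    with Path(path).open("w") as fh:
        if dialect.has_header:
            fh.write(
                dialect.delimiter.join(("protein_a", "protein_b", "combined_score"))
                + "\n"
            )
        for a, b, c in net.edges():
            score = f"{round(c * 1000):d}" if dialect.score_scale == "string" else repr(c)
            fh.write(dialect.delimiter.join((a, b, score)) + "\n")


def filter_by_confidence(
    net: InteractionNetwork,
    threshold: float,
    *,
    strict: bool = True,
    keep_isolated: bool = False,
) -> InteractionNetwork:
    """Keep edges with confidence > threshold (``strict=False`` for >=).

    Nodes left without edges are dropped unless ``keep_isolated``; the default
    mirrors a displayed-interactors network in which only connected proteins
    appear.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(net.graph.nodes)
    for a, b, c in net.edges():
        if c > threshold or (not strict and c == threshold):
            g.add_edge(a, b, confidence=c)
    return InteractionNetwork(g)


def largest_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest connected component.

    Ties on size are broken toward the component containing the
    lexicographically smallest node.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network has no components")
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return InteractionNetwork(net.graph.subgraph(comps[0]).copy())
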