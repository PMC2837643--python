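"""Undirected weighted protein-interaction networks.

The clustering substrate is a plain undirected graph over protein
identifiers with a non-negative weight per edge.  Storage is delegated to
:class:`networkx.Graph`; this wrapper enforces the two invariants the
analysis relies on — no self-edges, and a default weight of one for every
edge until semantic-similarity weighting is applied.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["WeightedNetwork", "union_networks"]


class WeightedNetwork:
    """Undirected protein graph with per-edge weights.

    Parameters
    ----------
    graph
        Optional pre-built :class:`networkx.Graph`.  Self-loops are removed
        (with a warning) and missing weights default to 1.
    """

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph() if graph is None else nx.Graph(graph)
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("dropping %d self-interaction(s)", len(loops))
            g.remove_edges_from(loops)
        for u, v, d in g.edges(data=True):
            d.setdefault("weight", 1.0)
        self.graph = g

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        weights: Iterable[float] | None = None,
    ) -> "WeightedNetwork":
        """Build a network from unordered protein pairs (default weight 1)."""
        g = nx.Graph()
        if weights is None:
            g.add_edges_from((a, b) for a, b in pairs)
        else:
            g.add_weighted_edges_from((a, b, w) for (a, b), w in zip(pairs, weights))
        return cls(g)

    # -- inspection -------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self.graph.edges())

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def set_weight(self, a: str, b: str, w: float) -> None:
        if w < 0:
            raise ValueError(f"negative edge weight {w!r} for ({a}, {b})")
        self.graph.edges[a, b]["weight"] = float(w)

    def add_node(self, n: str) -> None:
        self.graph.add_node(n)

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        if a == b:
            logger.warning("ignoring self-interaction %s-%s", a, b)
            return
        self.graph.add_edge(a, b, weight=float(weight))

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.graph.copy())

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges()}

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edge_set() == other.edge_set()
            and all(
                abs(self.weight(a, b) - other.weight(a, b)) < 1e-12
                for a, b in self.edges()
            )
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedNetwork({len(self)} proteins, {self.n_edges} interactions)"


def union_networks(networks: Iterable[WeightedNetwork]) -> WeightedNetwork:
    """Union of interaction sets across resources.

    Interactions carry no evidence multiplicity: a pair reported by several
    sources collapses to a single edge and every weight is reset to 1 (the
    unweighted state; semantic weighting is applied afterwards if at all).
    """
    g = nx.Graph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes)
        g.add_edges_from(net.graph.edges())
    for _, _, d in g.edges(data=True):
        d["weight"] = 1.0
    return WeightedNetwork(g)
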