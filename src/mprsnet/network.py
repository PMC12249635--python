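"""Node-weighted interaction network construction.

A trait-specific network is built by restricting a base protein-protein
interaction network to the genes that also carry a gene-level association
score, and weighting each remaining node with w = -log10(p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("mprsnet.network")

__all__ = ["WeightedNetwork", "build_weighted_network", "largest_connected_component"]


@dataclass
class WeightedNetwork:
    """Undirected gene graph with non-negative node weights.

    ``nodes`` is sorted for a stable adjacency-matrix ordering; weights are
    -log10 of the gene-level p-value.
    """

    graph: nx.Graph
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.graph.nodes) != set(self.weights):
            raise ValueError("weight keys must match graph nodes")
        for g, w in self.weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"node weight for {g!r} must be finite and >= 0, got {w}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[g] for g in self.nodes], dtype=float)

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, dtype=float)

    def degrees(self) -> np.ndarray:
        deg = dict(self.graph.degree)
        return np.array([deg[g] for g in self.nodes], dtype=float)

    def with_weights(self, weights: dict[str, float]) -> "WeightedNetwork":
        return WeightedNetwork(graph=self.graph, weights=weights)


def build_weighted_network(
    edges: list[tuple[str, str]],
    scores: pd.DataFrame,
    p_floor: float = 1e-300,
) -> WeightedNetwork:
    """Restrict a base edge list to scored genes and attach -log10(p) weights.

    Only genes present in both the edge list and the score table are kept;
    nodes isolated by the restriction are dropped.  ``p_floor`` bounds p
    away from zero so weights stay finite.
    """
    score_map = dict(zip(scores["gene_id"], scores["p_value"]))
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            continue
        if a in score_map and b in score_map:
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise ValueError("no overlap between edge-list genes and scored genes")
    weights = {v: float(-np.log10(max(score_map[v], p_floor))) for v in g.nodes}
    n_scored = len(score_map)
    logger.info(
        "build_weighted_network: %d/%d scored genes retained, %d edges",
        g.number_of_nodes(), n_scored, g.number_of_edges(),
    )
    return WeightedNetwork(graph=g, weights=weights)


def largest_connected_component(network: WeightedNetwork) -> WeightedNetwork:
    """Restrict to the largest connected component.

    Diffusion requires a connected graph with all degrees >= 1.  Ties in
    component size are broken toward the component containing the
    lexicographically smallest gene id.
    """
    comps = list(nx.connected_components(network.graph))
    if not comps:
        raise ValueError("empty network")
    max_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == max_size]
    best = min(tied, key=lambda c: min(c))
    if len(best) < network.n_nodes:
        logger.info(
            "largest_connected_component: kept %d/%d nodes", len(best), network.n_nodes
        )
    sub = network.graph.subgraph(best).copy()
    weights = {v: network.weights[v] for v in sub.nodes}
    return WeightedNetwork(graph=sub, weights=weights)
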