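"""Pathway network from flagged pairs, with maximal-clique-centrality hubs.

Each flagged pair becomes an undirected, unweighted edge between its two
pathways.  Hubs are ranked by Maximal Clique Centrality:

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!

so a node in one big clique outranks a node spread over many tiny ones.
A node with no triangles reduces to its degree (each incident edge is a
maximal 2-clique); an isolated node scores 0.  Cliques are enumerated
exactly with Bron-Kerbosch pivoting — the graphs here hold at most a few
dozen pathway nodes, so exact enumeration is cheap.
"""

from __future__ import annotations

import logging
from math import factorial

import networkx as nx

from .pairs import split_pair_id

logger = logging.getLogger(__name__)

__all__ = ["build_graph", "mcc_rank", "hub_subnetwork"]


def build_graph(flagged_pairs) -> nx.Graph:
    """Simple undirected graph whose edges are the given pair ids.

    Duplicate pairs collapse to one edge; self-pairs are rejected.
    """
    g = nx.Graph()
    for pair_id in flagged_pairs:
        a, b = split_pair_id(pair_id)
        if a == b:
            raise ValueError(f"self-pair {pair_id!r} cannot form an edge")
        g.add_edge(a, b)
    return g


def mcc_rank(graph: nx.Graph) -> list[tuple[str, int]]:
    """All nodes with their MCC scores, sorted by descending score then
    ascending node id (deterministic tie order)."""
    scores = {v: 0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue  # an isolated node is not a hub
        weight = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += weight
    return sorted(scores.items(), key=lambda item: (-item[1], item[0]))


def hub_subnetwork(graph: nx.Graph, ranking=None, top_n: int = 10) -> nx.Graph:
    """Induced subgraph on the ``top_n`` MCC-ranked nodes plus all their
    first neighbors."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if ranking is None:
        ranking = mcc_rank(graph)
    if top_n > graph.number_of_nodes():
        logger.warning(
            "top_n=%d exceeds the node count %d; returning the whole graph",
            top_n, graph.number_of_nodes(),
        )
        return graph.copy()
    hubs = [v for v, _ in ranking[:top_n]]
    keep = set(hubs)
    for v in hubs:
        keep.update(graph.neighbors(v))
    return graph.subgraph(keep).copy()
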