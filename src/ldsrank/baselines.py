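"""Comparison centralities for essential-protein ranking.

Seven classical node-importance measures, each returning a map from
protein ID to a finite non-negative score covering every network node:

- DC: degree centrality (raw degree).
- BC: betweenness centrality, unnormalized (sum over unordered pairs
  s < t of the fraction of s-t shortest paths through v).
- CloseC: closeness centrality, component-local:
  (n_component - 1) / sum of distances within the component; 0 for an
  isolated node.
- ClusterC: clustering coefficient 2 * e_N / (deg * (deg - 1)), where
  e_N is the edge count among neighbors; 0 when deg < 2.
- SC: subgraph centrality, the diagonal of exp(A) (sum over closed
  walks of length k weighted 1/k!).
- LAC: local average connectivity, the mean within-neighborhood degree
  of v's neighbors in the subgraph they induce; 0 for degree-0 nodes.
- LID: local interaction density, implemented as the interaction count
  among v's neighbors in the induced neighborhood.

BC and CloseC conventions are fixed as above and are component-local,
so disconnected networks are handled without special casing.
"""

from __future__ import annotations

from typing import Callable, Mapping

import networkx as nx

from ldsrank.graph_io import induced_neighborhood


def degree_centrality(net: nx.Graph) -> dict[str, float]:
    """Raw node degree."""
    return {v: float(d) for v, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness over unordered pairs."""
    return {v: float(b) for v, b in nx.betweenness_centrality(net, normalized=False).items()}


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """Component-local closeness (n_comp - 1) / sum-of-distances."""
    return {
        v: float(c)
        for v, c in nx.closeness_centrality(net, wf_improved=False).items()
    }


def clustering_coefficient(net: nx.Graph) -> dict[str, float]:
    """Local clustering coefficient; 0 when degree < 2."""
    return {v: float(c) for v, c in nx.clustering(net).items()}


def subgraph_centrality(net: nx.Graph) -> dict[str, float]:
    """Diagonal of the adjacency matrix exponential, per node.

    An isolated node scores exactly 1 (the k = 0 closed walk).
    """
    if net.number_of_nodes() == 0:
        return {}
    if net.number_of_edges() == 0:
        return {v: 1.0 for v in net.nodes()}
    return {v: float(s) for v, s in nx.subgraph_centrality(net).items()}


def lac(net: nx.Graph) -> dict[str, float]:
    """Local average connectivity.

    Mean degree of v's neighbors inside the subgraph induced by the
    neighbor set; 0 for isolated nodes.
    """
    out: dict[str, float] = {}
    for v in net.nodes():
        sub = induced_neighborhood(net, v)
        n = sub.number_of_nodes()
        out[v] = (2.0 * sub.number_of_edges() / n) if n else 0.0
    return out


def lid(net: nx.Graph) -> dict[str, float]:
    """Local interaction density: edge count among a node's neighbors."""
    return {
        v: float(induced_neighborhood(net, v).number_of_edges())
        for v in net.nodes()
    }


#: Registry of baseline methods by their conventional abbreviation.
METHODS: dict[str, Callable[[nx.Graph], Mapping[str, float]]] = {
    "DC": degree_centrality,
    "BC": betweenness_centrality,
    "CloseC": closeness_centrality,
    "ClusterC": clustering_coefficient,
    "SC": subgraph_centrality,
    "LAC": lac,
    "LID": lid,
}


def compute(net: nx.Graph, method: str) -> dict[str, float]:
    """Run one baseline by name (see :data:`METHODS`)."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; available: {', '.join(METHODS)}"
        ) from None
    return dict(fn(net))
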