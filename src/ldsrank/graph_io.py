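"""Read, clean, and query undirected PPI networks.

Networks are held as :class:`networkx.Graph` objects whose nodes are
protein-ID strings.  IDs are case-sensitive opaque strings; no
normalization is attempted.  Parsing enforces the usual cleaning applied
to interaction dumps: self-interactions are dropped and repeated
interactions (in either orientation) are collapsed to a single
undirected edge.

Disconnected networks are legal throughout the package; every per-node
quantity is computed within the node's own connected component.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Union

import networkx as nx

log = logging.getLogger(__name__)

Lines = Union[IO[str], Iterable[str]]


def read_edge_list(stream: Lines, delimiter: str = "\t") -> nx.Graph:
    """Parse a two-column edge list into a cleaned undirected network.

    Parameters
    ----------
    stream:
        An iterable of text lines (an open file works).  Blank lines and
        lines starting with ``#`` are skipped.  Each remaining line must
        have at least two delimited fields; the first two are the
        interacting protein IDs and any extra columns are ignored.
    delimiter:
        Field separator, tab by default.

    Returns
    -------
    networkx.Graph
        Simple undirected graph: no self-loops, no parallel edges.

    Raises
    ------
    ValueError
        If a non-comment line has fewer than two fields (the message
        carries the 1-based line number).
    """
    net = nx.Graph()
    n_self = 0
    n_dup = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ValueError(
                f"line {lineno}: expected at least 2 {delimiter!r}-separated "
                f"fields, got {len(fields)}: {line!r}"
            )
        u, v = fields[0].strip(), fields[1].strip()
        if not u or not v:
            raise ValueError(f"line {lineno}: empty protein ID in {line!r}")
        if u == v:
            n_self += 1
            net.add_node(u)
            continue
        if net.has_edge(u, v):
            n_dup += 1
            continue
        net.add_edge(u, v)
    log.info(
        "read edge list: %d nodes, %d edges, %d components "
        "(%d self-interactions dropped, %d repeated interactions collapsed)",
        net.number_of_nodes(),
        net.number_of_edges(),
        nx.number_connected_components(net) if net.number_of_nodes() else 0,
        n_self,
        n_dup,
    )
    return net


def write_edge_list(net: nx.Graph, handle: IO[str], delimiter: str = "\t") -> None:
    """Serialize a network back to a two-column edge list (sorted, stable)."""
    for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
        handle.write(f"{u}{delimiter}{v}\n")


def _require_node(net: nx.Graph, v: str) -> None:
    if v not in net:
        raise KeyError(f"protein {v!r} is not in the network")


def single_source_distances(net: nx.Graph, v: str) -> dict[str, int]:
    """Hop distances from ``v`` to every node in its connected component.

    The result maps target ID to unweighted shortest-path length,
    includes ``v`` itself at distance 0, and omits unreachable nodes.
    """
    _require_node(net, v)
    return dict(nx.single_source_shortest_path_length(net, v))


def eccentricity(net: nx.Graph, v: str) -> int:
    """Farthest hop distance from ``v`` within its component (0 if isolated)."""
    _require_node(net, v)
    return max(single_source_distances(net, v).values())


def induced_neighborhood(net: nx.Graph, v: str) -> nx.Graph:
    """Subgraph induced by the neighbors of ``v`` (``v`` itself excluded)."""
    _require_node(net, v)
    return net.subgraph(net[v]).copy()
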