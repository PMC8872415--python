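"""Deterministic example networks and synthetic PPI datasets.

Two small fixed networks pin down the fractal-dimension conventions:

- :func:`kite_network` -- the Krackhardt kite, a 10-node, 18-edge graph
  with a degree-6 hub (node "7") and a three-node tail, the canonical
  worked example for the fuzzy sphere values.
- :func:`ball_growth_tree` -- a 19-node tree whose center has cumulative
  sphere counts [6, 11, 15, 19] at radii 1..4, the worked example for
  the plain local fractal dimension.  Only those counts are normative;
  any tree realizing them yields the same fit.

The synthetic generators emulate the structure of real yeast PPI
datasets without requiring database downloads: a preferential-attachment
topology (scale-free-like degree distribution), an essential-protein set
planted with a degree bias (the centrality-lethality rule), and
compartment annotations in which a designated subset of compartments is
enriched for essential proteins.  All randomness flows through one
explicit integer seed; repeated calls are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from ldsrank.graph_io import write_edge_list
from ldsrank.subcellular import COMPARTMENTS, AnnotationTable

#: Compartments whose annotation probability is boosted for essential
#: proteins by the enrichment factor.
ESSENTIAL_RICH_COMPARTMENTS: tuple[str, ...] = (
    "Nucleus",
    "Mitochondrion",
    "Cytosol",
)

_KITE_EDGES = [
    ("1", "2"), ("1", "3"), ("1", "5"), ("1", "7"),
    ("2", "4"), ("2", "6"), ("2", "7"),
    ("3", "5"), ("3", "7"),
    ("4", "6"), ("4", "7"),
    ("5", "6"), ("5", "7"), ("5", "8"),
    ("6", "7"), ("6", "8"),
    ("8", "9"), ("9", "10"),
]


def kite_network() -> nx.Graph:
    """The Krackhardt kite, labeled "1".."10".

    Node "7" is the degree-6 hub; "8"-"9"-"10" is the tail, so the
    distance profile from the hub is six nodes at distance 1 and one
    node each at distances 2, 3 and 4.
    """
    net = nx.Graph()
    net.add_edges_from(_KITE_EDGES)
    return net


def ball_growth_tree() -> tuple[nx.Graph, str]:
    """A 19-node tree with sphere counts [6, 11, 15, 19] from its center.

    Construction: center ``v``; five children a1..a5; one grandchild
    under each child (b1..b5); four depth-3 nodes c1..c4 under b1..b4;
    four depth-4 nodes d1..d4 under c1..c4.  Returns (network, center).
    """
    net = nx.Graph()
    center = "v"
    for i in range(1, 6):
        net.add_edge(center, f"a{i}")
        net.add_edge(f"a{i}", f"b{i}")
    for i in range(1, 5):
        net.add_edge(f"b{i}", f"c{i}")
        net.add_edge(f"c{i}", f"d{i}")
    return net, center


def synthetic_ppi(n: int, m: int, seed: int) -> nx.Graph:
    """Preferential-attachment PPI-like network with string node IDs.

    Grows a Barabasi-Albert graph from an m-edge star: each of the
    n - m - 1 subsequent nodes attaches ``m`` edges preferentially, so
    the edge count is exactly (n - m) * m and the graph is connected.
    Nodes are relabeled "P0001", "P0002", ...  Deterministic per seed.
    """
    if not (m >= 1 and n >= m + 1):
        raise ValueError(f"need n >= m + 1 >= 2, got n={n}, m={m}")
    raw = nx.barabasi_albert_graph(n, m, seed=seed)
    width = len(str(n))
    mapping = {i: f"P{i + 1:0{width}d}" for i in raw.nodes()}
    return nx.relabel_nodes(raw, mapping)


def plant_essentials(
    net: nx.Graph, fraction: float, degree_bias: float, seed: int
) -> set[str]:
    """Sample an essential set biased toward high-degree nodes.

    Draws ceil(fraction * n) nodes without replacement with probability
    proportional to degree**degree_bias (uniform when degree_bias = 0).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if degree_bias < 0:
        raise ValueError(f"degree_bias must be >= 0, got {degree_bias}")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    weights = np.array([float(net.degree(v)) ** degree_bias for v in nodes])
    if weights.sum() == 0:
        weights = np.ones(len(nodes))
    k = int(np.ceil(fraction * len(nodes)))
    chosen = rng.choice(len(nodes), size=k, replace=False, p=weights / weights.sum())
    return {nodes[i] for i in chosen}


def plant_annotations(
    net: nx.Graph,
    essentials: set[str],
    enrichment: float,
    seed: int,
    unannotated_fraction: float = 0.05,
) -> AnnotationTable:
    """Assign 1-3 compartments per protein with essential-biased enrichment.

    Every protein is annotated except a random ``unannotated_fraction``.
    Compartments are drawn without replacement; for essential proteins
    the sampling weight of each compartment in
    :data:`ESSENTIAL_RICH_COMPARTMENTS` is multiplied by ``enrichment``
    (enrichment = 1 is the null model with no essentiality signal).
    """
    if enrichment < 1.0:
        raise ValueError(f"enrichment must be >= 1, got {enrichment}")
    rng = np.random.default_rng(seed)
    comps = list(COMPARTMENTS)
    rich = set(ESSENTIAL_RICH_COMPARTMENTS)
    base = np.ones(len(comps))
    boosted = np.array([enrichment if c in rich else 1.0 for c in comps])
    table = AnnotationTable()
    for v in sorted(net.nodes()):
        if rng.random() < unannotated_fraction:
            table.add(v, [])
            continue
        k = int(rng.integers(1, 4))
        w = boosted if v in essentials else base
        idx = rng.choice(len(comps), size=k, replace=False, p=w / w.sum())
        table.add(v, [comps[i] for i in idx])
    return table


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete synthetic ranking problem, reproducible from its seed."""

    network: nx.Graph
    essentials: set[str]
    annotations: AnnotationTable
    seed: int
    n_nodes: int
    attachment: int
    essential_fraction: float
    degree_bias: float
    enrichment: float

    @property
    def nonessentials(self) -> set[str]:
        return set(self.network.nodes()) - self.essentials


def make_synthetic_dataset(
    n: int = 1000,
    m: int = 3,
    fraction: float = 0.24,
    degree_bias: float = 2.0,
    enrichment: float = 5.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate network + essentials + annotations from one seed.

    Defaults mirror a yeast-interactome-like regime: mean degree around
    6, roughly a quarter of proteins essential, essentials biased toward
    hubs, and a strong (5x) localization signal.  Sub-seeds for the
    three stages are drawn from one ``numpy`` SeedSequence so the stages
    are independent but jointly reproducible.
    """
    s_net, s_ess, s_ann = np.random.SeedSequence(seed).generate_state(3)
    # networkx wants a Python int seed below 2**32
    net = synthetic_ppi(n, m, seed=int(s_net))
    essentials = plant_essentials(net, fraction, degree_bias, seed=int(s_ess))
    annotations = plant_annotations(net, essentials, enrichment, seed=int(s_ann))
    return SyntheticDataset(
        network=net,
        essentials=essentials,
        annotations=annotations,
        seed=seed,
        n_nodes=n,
        attachment=m,
        essential_fraction=fraction,
        degree_bias=degree_bias,
        enrichment=enrichment,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write edge list, essential/non-essential lists and annotation TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "edges.tsv", "w") as fh:
        write_edge_list(ds.network, fh)
    with open(outdir / "essentials.txt", "w") as fh:
        fh.writelines(f"{p}\n" for p in sorted(ds.essentials))
    with open(outdir / "nonessentials.txt", "w") as fh:
        fh.writelines(f"{p}\n" for p in sorted(ds.nonessentials))
    with open(outdir / "annotations.tsv", "w") as fh:
        for p in sorted(ds.annotations.entries):
            comps = ";".join(sorted(ds.annotations.compartments_of(p)))
            fh.write(f"{p}\t{comps}\n")
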