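"""Bipartite compound-target (C-T) network construction and topology metrics.

Nodes carry a partition label (compound or target); edges are predicted
interactions and always cross the partition.  Reported metrics follow the
conventions of Cytoscape's NetworkAnalyzer, which is what readers of
network-pharmacology studies expect:

* degree — number of incident edges;
* betweenness — Brandes' algorithm on the whole (undirected) graph,
  normalized by 2/((n−1)(n−2));
* network centralization — (n/(n−2)) · (max_deg/(n−1) − density), 1 for a
  star and 0 for any regular graph;
* network heterogeneity — coefficient of variation of the degree
  distribution, sqrt(population variance)/mean.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "CTNetwork",
    "NetworkSummary",
    "build_network",
    "degree_all",
    "betweenness_all",
    "centralization",
    "heterogeneity",
    "hub_rank",
    "mean_targets_per_compound",
    "summarize_network",
    "export_network",
    "import_network",
]

logger = logging.getLogger(__name__)

COMPOUND, TARGET = "compound", "target"


@dataclass
class CTNetwork:
    """Undirected bipartite compound-target graph (NetworkX-backed)."""

    graph: nx.Graph

    @property
    def compounds(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["partition"] == COMPOUND)

    @property
    def targets(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["partition"] == TARGET)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_compounds: int
    n_targets: int
    centralization: float
    heterogeneity: float
    mean_compound_degree: float
    mean_target_degree: float


def build_network(
    pairs: list[tuple[str, str]],
    compounds: list[str] | None = None,
    targets: list[str] | None = None,
) -> CTNetwork:
    """Build the deduplicated bipartite graph from (compound, target) pairs.

    Declared but unpaired compounds/targets are kept as isolated nodes.
    A node appearing on both sides of the partition raises.
    """
    g = nx.Graph()
    compound_set = set(compounds or [])
    target_set = set(targets or [])
    for c, t in pairs:
        compound_set.add(c)
        target_set.add(t)
    clash = compound_set & target_set
    if clash:
        raise ValueError(f"nodes appear in both partitions: {sorted(clash)[:5]}")
    for c in compound_set:
        g.add_node(c, partition=COMPOUND)
    for t in target_set:
        g.add_node(t, partition=TARGET)
    for c, t in pairs:
        g.add_edge(c, t)
    return CTNetwork(graph=g)


def degree_all(net: CTNetwork) -> dict[str, int]:
    return dict(net.graph.degree())


def betweenness_all(net: CTNetwork) -> dict[str, float]:
    """Normalized betweenness (Brandes); all zeros for n < 3."""
    if net.n_nodes < 3:
        return {node: 0.0 for node in net.graph}
    return nx.betweenness_centrality(net.graph, normalized=True)


def centralization(net: CTNetwork) -> float:
    """Degree centralization: (n/(n−2))·(max_deg/(n−1) − density)."""
    n = net.n_nodes
    if n < 3:
        raise ValueError("centralization needs at least 3 nodes")
    m = net.n_edges
    max_deg = max(d for _, d in net.graph.degree())
    density = 2 * m / (n * (n - 1))
    return (n / (n - 2)) * (max_deg / (n - 1) - density)


def heterogeneity(net: CTNetwork) -> float:
    """Coefficient of variation of the degree distribution."""
    degrees = [d for _, d in net.graph.degree()]
    if not degrees:
        raise ValueError("heterogeneity of an empty network is undefined")
    mu = sum(degrees) / len(degrees)
    if mu == 0:
        raise ValueError("heterogeneity undefined when every node is isolated")
    var = sum((d - mu) ** 2 for d in degrees) / len(degrees)
    return math.sqrt(var) / mu


def hub_rank(net: CTNetwork, k: int, partition: str | None = None) -> list[str]:
    """Top-k hubs by degree, ties broken by betweenness then node id.

    ``partition`` restricts ranking to "compound" or "target" nodes.
    """
    degrees = degree_all(net)
    between = betweenness_all(net)
    nodes = list(net.graph)
    if partition is not None:
        nodes = [v for v in nodes if net.graph.nodes[v]["partition"] == partition]
    nodes.sort(key=lambda v: (-degrees[v], -between[v], v))
    if k > len(nodes):
        logger.info("hub_rank: k=%d exceeds node count %d; returning all", k, len(nodes))
    return nodes[:max(0, k)]


def mean_targets_per_compound(net: CTNetwork) -> tuple[float, int]:
    """Edges per compound node: (exact value, integer truncation)."""
    n_compounds = len(net.compounds)
    if n_compounds == 0:
        raise ValueError("network has no compound nodes")
    exact = net.n_edges / n_compounds
    return exact, int(exact)


def summarize_network(net: CTNetwork) -> NetworkSummary:
    compounds, targets = net.compounds, net.targets
    degrees = degree_all(net)
    mean_c = sum(degrees[c] for c in compounds) / len(compounds) if compounds else 0.0
    mean_t = sum(degrees[t] for t in targets) / len(targets) if targets else 0.0
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        n_compounds=len(compounds),
        n_targets=len(targets),
        centralization=centralization(net) if net.n_nodes >= 3 else float("nan"),
        heterogeneity=heterogeneity(net),
        mean_compound_degree=mean_c,
        mean_target_degree=mean_t,
    )


# ---------------------------------------------------------------------------
# Cytoscape interchange


def export_network(net: CTNetwork) -> tuple[str, str]:
    """Serialize as (SIF text, node-attribute TSV) with deterministic ordering.

    SIF lines read "compound ct target"; isolated nodes appear as bare
    single-column SIF lines so re-import preserves them.
    """
    sif_lines = []
    for c in net.compounds:
        neighbors = sorted(net.graph.neighbors(c))
        if neighbors:
            sif_lines.append(f"{c}\tct\t" + "\t".join(neighbors))
    for node in sorted(nx.isolates(net.graph)):
        sif_lines.append(str(node))
    sif = "\n".join(sif_lines) + ("\n" if sif_lines else "")

    degrees = degree_all(net)
    between = betweenness_all(net)
    rows = [
        {
            "node_id": v,
            "partition": net.graph.nodes[v]["partition"],
            "degree": degrees[v],
            "betweenness": round(between[v], 6),
        }
        for v in sorted(net.graph)
    ]
    buf = io.StringIO()
    pd.DataFrame(rows, columns=["node_id", "partition", "degree", "betweenness"]).to_csv(
        buf, sep="\t", index=False
    )
    return sif, buf.getvalue()


def import_network(sif_text: str, attr_tsv: str) -> CTNetwork:
    """Rebuild a network from the export_network pair."""
    attrs = pd.read_csv(io.StringIO(attr_tsv), sep="\t", dtype={"node_id": str})
    partition = dict(zip(attrs["node_id"], attrs["partition"]))
    pairs = []
    declared_c = [v for v, p in partition.items() if p == COMPOUND]
    declared_t = [v for v, p in partition.items() if p == TARGET]
    for line in sif_text.splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 3 and fields[1] == "ct":
            pairs.extend((fields[0], t) for t in fields[2:])
    return build_network(pairs, compounds=declared_c, targets=declared_t)
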