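"""Partially directed, signed association networks from significant pairs.

An edge is kept when its record passes both the p-value and q-value
thresholds.  The edge sign is the sign of the LS score (positive: co-varying;
negative: contrary-varying).  Direction follows the aligned interval starts:
if X's interval starts earlier than Y's (``xs < ys``), X leads Y — X possibly
activates Y; equal starts leave the edge undirected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx

X_LEADS_Y = "x_leads_y"
Y_LEADS_X = "y_leads_x"
UNDIRECTED = "undirected"


@dataclass
class AssociationNetwork:
    """Signed, partially directed graph over factors.

    Backed by an undirected :class:`networkx.Graph`; lead/lag information is
    carried by the per-edge ``direction`` attribute rather than by arc
    orientation, since only some edges are directed.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return [(u, v, data) for u, v, data in self.graph.edges(data=True)]


def build_network(
    records,
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> AssociationNetwork:
    """Filter records by significance and assemble the association graph."""
    g = nx.Graph()
    for rec in records:
        if rec.q is None or rec.p is None:
            raise ValueError(
                f"record ({rec.x_id}, {rec.y_id}) lacks a p- or q-value; "
                "run the full pipeline (permutations enabled) first"
            )
        if rec.p > p_threshold or rec.q > q_threshold:
            continue
        if rec.xs < rec.ys:
            direction = X_LEADS_Y
        elif rec.xs > rec.ys:
            direction = Y_LEADS_X
        else:
            direction = UNDIRECTED
        g.add_edge(
            rec.x_id, rec.y_id,
            sign=1 if rec.ls >= 0 else -1,
            direction=direction,
            ls=float(rec.ls),
            p=float(rec.p),
            q=float(rec.q),
            delay=int(rec.delay),
        )
    return AssociationNetwork(g)


class DegreeSummary(NamedTuple):
    counts: dict  # degree -> number of nodes
    mean_degree: float


def degree_distribution(network: AssociationNetwork) -> DegreeSummary:
    """Undirected degree histogram and mean degree over connected nodes.

    Direction attributes are ignored.  The mean is taken over nodes carrying
    at least one edge (isolated nodes, if any were added externally, do not
    dilute it); switch to an all-nodes denominator by dividing
    ``2 * |edges| / |nodes|`` yourself if preferred.
    """
    degrees = dict(network.graph.degree())
    counts = dict(Counter(degrees.values()))
    connected = sum(1 for d in degrees.values() if d >= 1)
    n_edges = network.graph.number_of_edges()
    mean = 2.0 * n_edges / connected if connected else 0.0
    return DegreeSummary(counts, mean)


def export_network(network: AssociationNetwork, basename: str) -> dict[str, str]:
    """Write SIF, edge-attribute TSV and GraphML renditions.

    SIF uses interaction tokens ``pa`` (positive association) and ``na``
    (negative association) so Cytoscape can style solid vs dashed edges.
    Returns the mapping of format name to file path.
    """
    paths = {
        "sif": f"{basename}.sif",
        "edges": f"{basename}.edges.tsv",
        "graphml": f"{basename}.graphml",
    }
    with open(paths["sif"], "wt", encoding="utf-8") as fh:
        for u, v, data in network.graph.edges(data=True):
            token = "pa" if data["sign"] > 0 else "na"
            fh.write(f"{u}\t{token}\t{v}\n")
    with open(paths["edges"], "wt", encoding="utf-8") as fh:
        fh.write("edge\tls\tp\tq\tdelay\tdirection\n")
        for u, v, data in network.graph.edges(data=True):
            token = "pa" if data["sign"] > 0 else "na"
            fh.write(
                f"{u} ({token}) {v}\t{data['ls']:.6g}\t{data['p']:.6g}\t"
                f"{data['q']:.6g}\t{data['delay']}\t{data['direction']}\n"
            )
    nx.write_graphml(network.graph, paths["graphml"])
    return paths
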