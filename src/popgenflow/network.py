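"""Haplotype network: minimum spanning tree/network over mutational steps.

The network connects haplotypes by edges weighted with their Hamming
distance over the segregating sites (mutational steps), each edge annotated
with the 1-based alignment positions at which its endpoints differ.  With
``keep_alternate_minimal_edges`` every non-tree connection whose weight ties
the heaviest edge on its tree cycle is retained, giving a minimum spanning
network (the loops a statistical-parsimony network would also show at these
shallow divergences).  No parsimony connection limit is applied and no
unsampled intermediate haplotypes are inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import HaplotypeTable


@dataclass
class HaplotypeNetwork:
    """Nodes carry counts; edges carry mutational steps and positions."""

    graph: nx.Graph
    is_tree: bool

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "hap_i": u,
                "hap_j": v,
                "steps": data["steps"],
                "positions": ",".join(str(p) for p in data["positions"]),
                "in_tree": data["in_tree"],
            }
            for u, v, data in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["hap_i", "hap_j", "steps", "positions", "in_tree"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in sorted(self.graph.nodes(data=True)):
            row = {"haplotype": node, "states": data["states"], "count": data["count"]}
            row.update(data["per_population"])
            rows.append(row)
        return pd.DataFrame(rows)


def _differing_positions(h: HaplotypeTable, i: int, j: int) -> list[int]:
    return [pos for pos, a, b in zip(h.site_positions, h.haplotypes[i], h.haplotypes[j])
            if a != b]


def build_network(h: HaplotypeTable,
                  keep_alternate_minimal_edges: bool = False) -> HaplotypeNetwork:
    """Build the haplotype MST (or minimum spanning network).

    Candidate edges are sorted by (steps, hap_i, hap_j) and added greedily
    (Kruskal with deterministic tie-breaking).  With the flag set, each
    rejected edge is kept whenever its weight equals the maximum weight on
    the tree path between its endpoints (an equally minimal alternative).
    """
    names = list(h.counts.index)
    k = len(names)
    dist = h.distance_matrix()
    totals = h.total_counts()

    g = nx.Graph()
    for idx, name in enumerate(names):
        g.add_node(name, states=h.haplotypes[idx], count=int(totals[name]),
                   per_population={p: int(h.counts.loc[name, p]) for p in h.counts.columns})
    if k == 1:
        return HaplotypeNetwork(g, is_tree=True)

    edges = sorted(
        (int(dist[i, j]), names[i], names[j], i, j)
        for i in range(k) for j in range(i + 1, k)
    )
    tree = nx.Graph()
    tree.add_nodes_from(names)
    rejected = []
    for steps, u, v, i, j in edges:
        if nx.has_path(tree, u, v):
            rejected.append((steps, u, v, i, j))
        else:
            tree.add_edge(u, v, weight=steps)
            g.add_edge(u, v, steps=steps, positions=_differing_positions(h, i, j),
                       in_tree=True)

    is_tree = True
    if keep_alternate_minimal_edges:
        for steps, u, v, i, j in rejected:
            path = nx.shortest_path(tree, u, v)
            max_on_cycle = max(tree[a][b]["weight"] for a, b in zip(path, path[1:]))
            if steps <= max_on_cycle:
                g.add_edge(u, v, steps=steps, positions=_differing_positions(h, i, j),
                           in_tree=False)
                is_tree = False
    return HaplotypeNetwork(g, is_tree=is_tree)
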