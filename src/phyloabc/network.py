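"""Unrooted minimum-spanning haplotype networks.

The network is the epsilon = 0 minimum spanning network (the union of all
minimum spanning trees): edges between distinct haplotypes are considered
in ascending Hamming-distance order, and within each weight class *all*
edges joining components that were distinct before that class are kept —
ties are not broken.  Edge weight is the number of mutational steps
(Hamming distance over the full sequences).  Median (inferred) vertices
are deliberately not added.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import HaplotypeTable

__all__ = ["build_msn", "export_network", "mst_weight"]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_msn(haps: HaplotypeTable) -> nx.Graph:
    """Minimum spanning network over the distinct haplotypes of one locus.

    Node attributes: ``count`` (total copies), ``count_<REGION>`` per
    region, ``sequence``.  Edge attribute ``mutations`` is the Hamming
    distance.  The returned graph is connected and contains every minimum
    spanning tree of the haplotype distance matrix.
    """
    H = haps.n_haplotypes
    if H == 0:
        raise ValueError("empty haplotype table")
    g = nx.Graph(locus=haps.locus)
    for i in range(H):
        attrs = {"count": int(haps.counts[i]), "sequence": haps.sequences[i]}
        for region in haps.region_counts.columns:
            attrs[f"count_{region}"] = int(haps.region_counts.loc[i, region])
        g.add_node(i, **attrs)
    if H == 1:
        return g
    d = np.zeros((H, H), dtype=int)
    for i in range(H):
        for j in range(i + 1, H):
            d[i, j] = d[j, i] = _hamming(haps.sequences[i], haps.sequences[j])
    # Kruskal sweep by weight class, keeping all tied bridging edges
    comp = list(range(H))

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    weights = np.unique(d[np.triu_indices(H, k=1)])
    for w in weights:
        # edges of this weight judged against components before the class
        snapshot = [find(i) for i in range(H)]
        batch = [
            (i, j)
            for i in range(H)
            for j in range(i + 1, H)
            if d[i, j] == w and snapshot[i] != snapshot[j]
        ]
        for i, j in batch:
            g.add_edge(i, j, mutations=int(w))
        for i, j in batch:
            ri, rj = find(i), find(j)
            if ri != rj:
                comp[ri] = rj
        if len({find(i) for i in range(H)}) == 1:
            break
    return g


def mst_weight(g: nx.Graph) -> int:
    """Total weight of a minimum spanning tree inside the network."""
    t = nx.minimum_spanning_tree(g, weight="mutations")
    return int(sum(d["mutations"] for _, _, d in t.edges(data=True)))


def export_network(g: nx.Graph, graphml_path: str, edges_tsv_path: str) -> None:
    """GraphML plus a companion tab-delimited edge list.

    Node order in both files follows the haplotype table's deterministic
    ordering (descending count, then lexicographic sequence).
    """
    nx.write_graphml(g, graphml_path)
    rows = [
        {"from": min(u, v), "to": max(u, v), "mutations": d["mutations"]}
        for u, v, d in g.edges(data=True)
    ]
    rows.sort(key=lambda r: (r["from"], r["to"]))
    df = pd.DataFrame(rows, columns=["from", "to", "mutations"])
    df.to_csv(edges_tsv_path, sep="\t", index=False)
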