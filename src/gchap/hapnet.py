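"""Minimum-spanning haplotype networks.

Haplotypes are connected in the statistical-parsimony spirit: the most
closely related pairs (fewest mutation steps, i.e. smallest Hamming
distance between allele vectors) are joined first, Kruskal-style.  Edges
that would re-join two already-connected haplotypes at the same step count
at which their components merged are kept as alternative links
(reticulations, ``in_msn=False``).  An optional connection limit drops all
edges above a step threshold, which can split the network into
subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gchap_core import GcHapTable


@dataclass
class NetEdge:
    hap_a: str
    hap_b: str
    steps: int
    in_msn: bool


@dataclass
class HapNetwork:
    gene_id: str
    nodes: list[str]                              # hap ids in rank order
    node_count: dict[str, int]                    # global frequency count
    node_populations: dict[str, dict[str, int]]   # per-population composition
    edges: list[NetEdge] = field(default_factory=list)
    connection_limit: int | None = None

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for h in self.nodes:
            g.add_node(h, count=self.node_count[h],
                       populations=self.node_populations[h])
        for e in self.edges:
            g.add_edge(e.hap_a, e.hap_b, steps=e.steps, in_msn=e.in_msn)
        return g


def pairwise_steps(table: GcHapTable) -> np.ndarray:
    """Hamming distance matrix between haplotype allele vectors.

    Symmetric with a zero diagonal; haplotypes are ordered by Hap rank.
    """
    vectors = [h.allele_vector for h in table.haplotypes]
    lengths = {len(v) for v in vectors}
    if len(lengths) > 1:
        raise ValueError(
            f"gene {table.gene_id}: allele vectors of unequal length {lengths}"
        )
    mat = np.array(vectors, dtype=np.int16)
    if mat.size == 0:
        return np.zeros((len(vectors), len(vectors)), dtype=np.int64)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(np.int64)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_network(table: GcHapTable, limit: int | None = None) -> HapNetwork:
    """Build the haplotype network for one gene.

    Candidate edges (all haplotype pairs with steps <= ``limit``, if set)
    are processed in (steps ascending, Hap-rank pair ascending) order.  An
    edge joining two components becomes a spanning edge (``in_msn=True``);
    an edge inside one component is retained as an alternative link iff its
    step count equals the step at which its endpoints first became
    connected.  Deterministic for a fixed haplotype naming.
    """
    haps = [h.hap_id for h in table.haplotypes]
    n = len(haps)
    net = HapNetwork(
        gene_id=table.gene_id,
        nodes=haps,
        node_count={h.hap_id: h.global_count for h in table.haplotypes},
        node_populations={h.hap_id: dict(h.per_population_count)
                          for h in table.haplotypes},
        connection_limit=limit,
    )
    if n <= 1:
        return net
    dist = pairwise_steps(table)
    candidates = [
        (int(dist[i, j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if limit is None or dist[i, j] <= limit
    ]
    candidates.sort()
    uf = _UnionFind(n)
    # conn_step[i][j]: step count at which i and j first became connected
    conn_step = np.full((n, n), -1, dtype=np.int64)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for steps, i, j in candidates:
        ri, rj = uf.find(i), uf.find(j)
        if ri != rj:
            for u in members[ri]:
                for v in members[rj]:
                    conn_step[u, v] = conn_step[v, u] = steps
            uf.union(ri, rj)
            root = uf.find(ri)
            merged = members.pop(ri) + members.pop(rj)
            members[root] = merged
            net.edges.append(NetEdge(haps[i], haps[j], steps, in_msn=True))
        elif steps == conn_step[i, j]:
            net.edges.append(NetEdge(haps[i], haps[j], steps, in_msn=False))
    return net


def export_network(net: HapNetwork, node_path: str, edge_path: str) -> None:
    """Write the network as a node TSV and an edge TSV.

    The node table carries per-population counts (one ``n_<pop>`` column per
    population seen), enabling pie-style composition annotation downstream.
    """
    pops = sorted({p for comp in net.node_populations.values() for p in comp})
    node_rows = []
    for h in net.nodes:
        row = {"hap_id": h, "count": net.node_count[h]}
        for p in pops:
            row[f"n_{p}"] = net.node_populations[h].get(p, 0)
        node_rows.append(row)
    pd.DataFrame(node_rows).to_csv(node_path, sep="\t", index=False)
    edge_rows = [
        {"hap_a": e.hap_a, "hap_b": e.hap_b, "steps": e.steps, "in_msn": e.in_msn}
        for e in net.edges
    ]
    pd.DataFrame(edge_rows, columns=["hap_a", "hap_b", "steps", "in_msn"]).to_csv(
        edge_path, sep="\t", index=False
    )


def read_network(node_path: str, edge_path: str,
                 gene_id: str = "", limit: int | None = None) -> HapNetwork:
    """Read back a node/edge TSV pair written by :func:`export_network`."""
    nodes_df = pd.read_csv(node_path, sep="\t", dtype={"hap_id": str})
    edges_df = pd.read_csv(edge_path, sep="\t", dtype={"hap_a": str, "hap_b": str})
    pop_cols = [c for c in nodes_df.columns if c.startswith("n_")]
    net = HapNetwork(
        gene_id=gene_id,
        nodes=list(nodes_df["hap_id"]),
        node_count={r["hap_id"]: int(r["count"]) for _, r in nodes_df.iterrows()},
        node_populations={
            r["hap_id"]: {c[2:]: int(r[c]) for c in pop_cols if r[c] > 0}
            for _, r in nodes_df.iterrows()
        },
        connection_limit=limit,
    )
    for _, r in edges_df.iterrows():
        net.edges.append(NetEdge(r["hap_a"], r["hap_b"], int(r["steps"]),
                                 bool(r["in_msn"])))
    return net
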