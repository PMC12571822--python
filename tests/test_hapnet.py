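import itertools

import networkx as nx
import numpy as np
import pytest

from gchap import build_network, export_network, pairwise_steps, read_network
from gchap.gchap_core import GcHap, GcHapTable
from util import table_from_hap_indices


def table_from_vectors(vectors, counts=None, gene_id="g"):
    counts = counts or list(range(len(vectors), 0, -1))
    order = sorted(range(len(vectors)), key=lambda i: (-counts[i], i))
    haps = [
        GcHap(hap_id=f"Hap{r + 1}", allele_vector=tuple(vectors[i]),
              global_count=counts[i],
              per_population_count={"Xian": counts[i]})
        for r, i in enumerate(order)
    ]
    assignment = {}
    acc = 0
    for h in haps:
        for _ in range(h.global_count):
            assignment[f"A{acc:04d}"] = h.hap_id
            acc += 1
    return GcHapTable(gene_id=gene_id,
                      site_positions=tuple(range(len(vectors[0]))),
                      haplotypes=haps, assignment=assignment, excluded_count=0)


def prufer_trees(n):
    """All labeled spanning trees on n nodes via Prüfer sequences."""
    import heapq

    if n == 1:
        yield []
        return
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        heap = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(heap)
        edges = []
        for x in seq:
            leaf = heapq.heappop(heap)
            edges.append((leaf, x))
            degree[x] -= 1
            if degree[x] == 1:
                heapq.heappush(heap, x)
        edges.append((heapq.heappop(heap), heapq.heappop(heap)))
        yield edges


class TestPairwiseSteps:
    def test_zero_distance_and_simple_counts(self):
        t = table_from_vectors([(0, 0, 0), (0, 1, 1)])
        d = pairwise_steps(t)
        assert d[0, 0] == 0 and d[1, 1] == 0
        assert d[0, 1] == d[1, 0] == 2

    def test_matches_per_site_brute_force(self):
        rng = np.random.default_rng(4)
        vectors = [tuple(rng.integers(0, 3, 6)) for _ in range(10)]
        vectors = list(dict.fromkeys(vectors))
        t = table_from_vectors(vectors)
        d = pairwise_steps(t)
        for i, vi in enumerate(vectors):
            for j, vj in enumerate(vectors):
                assert d[i, j] == sum(a != b for a, b in zip(vi, vj))

    def test_length_mismatch_is_an_error(self):
        t = table_from_vectors([(0, 0)])
        t.haplotypes.append(GcHap("HapX", (0, 0, 0), 1))
        with pytest.raises(ValueError, match="unequal length"):
            pairwise_steps(t)


class TestBuildNetwork:
    def test_chain_of_single_step_mutations(self):
        t = table_from_vectors([(0, 0, 0), (0, 0, 1), (0, 1, 1)], [3, 2, 1])
        net = build_network(t)
        spanning = {(e.hap_a, e.hap_b) for e in net.edges if e.in_msn}
        assert spanning == {("Hap1", "Hap2"), ("Hap2", "Hap3")}
        assert all(e.steps == 1 for e in net.edges if e.in_msn)
        # the distance-2 Hap1-Hap3 edge exceeds the merge step and is dropped
        assert len(net.edges) == 2

    def test_single_haplotype(self):
        net = build_network(table_from_vectors([(0, 0)]))
        assert net.nodes == ["Hap1"]
        assert net.edges == []

    def test_connection_limit_splits_network(self):
        t = table_from_vectors([(0, 0, 0), (1, 1, 1)], [2, 1])
        net = build_network(t, limit=2)
        assert net.edges == []
        g = net.to_networkx()
        assert nx.number_connected_components(g) == 2

    def test_unlimited_network_is_connected_with_no_zero_edges(self):
        rng = np.random.default_rng(6)
        vectors = list(dict.fromkeys(
            tuple(rng.integers(0, 2, 8)) for _ in range(12)))
        net = build_network(table_from_vectors(vectors))
        g = net.to_networkx()
        assert nx.is_connected(g)
        assert all(e.steps >= 1 for e in net.edges)

    def test_spanning_weight_equals_exhaustive_minimum(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            vectors = list(dict.fromkeys(
                tuple(rng.integers(0, 2, 7)) for _ in range(6)))
            n = len(vectors)
            t = table_from_vectors(vectors)
            d = pairwise_steps(t)
            best = min(
                sum(d[u, v] for u, v in edges) for edges in prufer_trees(n)
            )
            net = build_network(t)
            msn_weight = sum(e.steps for e in net.edges if e.in_msn)
            assert msn_weight == best

    def test_spanning_weight_matches_networkx_mst(self):
        rng = np.random.default_rng(14)
        vectors = list(dict.fromkeys(
            tuple(rng.integers(0, 2, 10)) for _ in range(15)))
        t = table_from_vectors(vectors)
        d = pairwise_steps(t)
        g = nx.Graph()
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                g.add_edge(i, j, weight=int(d[i, j]))
        expected = sum(
            data["weight"]
            for _, _, data in nx.minimum_spanning_tree(g).edges(data=True))
        net = build_network(t)
        assert sum(e.steps for e in net.edges if e.in_msn) == expected

    def test_alternative_links_marked_not_msn(self):
        # square: four vectors pairwise one step around a cycle
        vectors = [(0, 0), (0, 1), (1, 0), (1, 1)]
        net = build_network(table_from_vectors(vectors))
        msn = [e for e in net.edges if e.in_msn]
        alt = [e for e in net.edges if not e.in_msn]
        assert len(msn) == 3
        assert len(alt) == 1
        assert alt[0].steps == 1

    def test_recovers_generating_mutation_tree(self, sim_tables, sim_result):
        # each site mutates once, so distance-1 pairs are exactly the
        # parent-child edges of the generating tree; with every haplotype
        # sampled, the spanning edges must reproduce that tree
        checked_full = 0
        for table, truth in zip(sim_tables, sim_result.genes):
            net = build_network(table)
            vec_to_idx = {tuple(v): i for i, v in enumerate(truth.hap_vectors)}
            called = {h.hap_id: vec_to_idx[h.allele_vector]
                      for h in table.haplotypes}
            tree_edges = {frozenset((p, c)) for p, c, _ in truth.tree_edges}
            got_msn = {frozenset((called[e.hap_a], called[e.hap_b]))
                       for e in net.edges if e.in_msn}
            if len(called) == len(truth.hap_vectors):
                assert got_msn == tree_edges
                checked_full += 1
            else:
                one_step = {frozenset((called[e.hap_a], called[e.hap_b]))
                            for e in net.edges if e.steps == 1}
                sampled_tree = {
                    fe for fe in tree_edges
                    if fe <= set(called.values())
                }
                assert sampled_tree <= one_step
        assert checked_full >= 1


class TestExportNetwork:
    def test_round_trip(self, tmp_path):
        t, _ = table_from_hap_indices([0] * 5 + [1] * 3, [2] * 2)
        net = build_network(t)
        node_p, edge_p = tmp_path / "n.tsv", tmp_path / "e.tsv"
        export_network(net, str(node_p), str(edge_p))
        back = read_network(str(node_p), str(edge_p), gene_id=net.gene_id)
        assert back.nodes == net.nodes
        assert back.node_count == net.node_count
        assert [(e.hap_a, e.hap_b, e.steps, e.in_msn) for e in back.edges] == \
            [(e.hap_a, e.hap_b, e.steps, e.in_msn) for e in net.edges]

    def test_single_node_network_exports(self, tmp_path):
        net = build_network(table_from_vectors([(0,)]))
        node_p, edge_p = tmp_path / "n.tsv", tmp_path / "e.tsv"
        export_network(net, str(node_p), str(edge_p))
        back = read_network(str(node_p), str(edge_p))
        assert back.nodes == ["Hap1"]
        assert back.edges == []

    def test_population_counts_conserved(self, sim_tables, tmp_path):
        table = sim_tables[0]
        net = build_network(table)
        for h in net.nodes:
            assert sum(net.node_populations[h].values()) == net.node_count[h]
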