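"""Community detection: partition validity, modularity, recovery, extraction."""
import itertools

import networkx as nx
import numpy as np
import pytest

from mirgrn import (GeneratorConfig, MirnaGRN, community_of, community_sizes,
                    detect_communities, extract_community, gen_gene_network,
                    largest_community_id, modularity_score, planted_labels)
from mirgrn.community import ABSENT
from mirgrn.errors import ConsistencyError, ParameterError
from tests.conftest import random_grn


def brute_force_best_modularity(graph):
    """Exhaustive modularity maximization over all partitions (tiny graphs)."""
    nodes = sorted(graph.nodes())

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1:]
            yield part + [[first]]

    return max(modularity_score(graph, p) for p in partitions(nodes))


class TestDetectCommunities:
    def test_two_cliques_are_separated_at_the_exhaustive_optimum(
            self, two_clique_grn):
        part = detect_communities(two_clique_grn, "fast_greedy", seed=0)
        groups = {frozenset(c) for c in part.communities()}
        assert groups == {frozenset({"a1", "a2", "a3", "a4"}),
                          frozenset({"b1", "b2", "b3", "b4"})}
        assert part.modularity > 0
        g = nx.Graph()
        g.add_edges_from(two_clique_grn.gene_edges)
        assert part.modularity == pytest.approx(
            brute_force_best_modularity(g), abs=1e-12)

    def test_single_clique_is_one_community_with_zero_modularity(self):
        grn = MirnaGRN(gene_edges=list(itertools.combinations("abcd", 2)))
        part = detect_communities(grn)
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_empty_network_is_an_error(self):
        with pytest.raises(ParameterError):
            detect_communities(MirnaGRN())

    def test_edgeless_network_gives_singletons(self):
        grn = MirnaGRN(gene_nodes=["a", "b", "c"])
        part = detect_communities(grn)
        assert part.n_communities == 3
        assert part.modularity == 0.0

    @pytest.mark.parametrize("method", ["fast_greedy", "louvain"])
    def test_deterministic_for_fixed_input_and_seed(self, method):
        grn = random_grn(np.random.default_rng(5))
        p1 = detect_communities(grn, method, seed=42)
        p2 = detect_communities(grn, method, seed=42)
        assert p1.assignment == p2.assignment
        assert p1.modularity == p2.modularity

    @pytest.mark.parametrize("method", ["fast_greedy", "louvain"])
    @pytest.mark.parametrize("seed", range(3))
    def test_partition_is_valid_and_modularity_recomputes(self, method, seed):
        grn = random_grn(np.random.default_rng(seed))
        part = detect_communities(grn, method, seed=seed)
        assert set(part.assignment) == grn.nodes          # full coverage
        ids = sorted(set(part.assignment.values()))
        assert ids == list(range(1, len(ids) + 1))        # contiguous from 1
        g = nx.Graph()
        g.add_nodes_from(grn.nodes)
        g.add_edges_from(grn.graph.edges())
        # independent recomputation via networkx's modularity
        assert part.modularity == pytest.approx(
            nx.community.modularity(g, part.communities()), abs=1e-9)

    def test_modularity_agrees_with_igraph(self):
        igraph = pytest.importorskip("igraph")
        grn = random_grn(np.random.default_rng(9))
        part = detect_communities(grn)
        nodes = sorted(grn.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        g = igraph.Graph(n=len(nodes),
                         edges=[(index[u], index[v])
                                for u, v in grn.graph.edges()])
        membership = [part.assignment[n] - 1 for n in nodes]
        assert part.modularity == pytest.approx(
            g.modularity(membership), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_partition_recovery(self, seed):
        from sklearn.metrics import adjusted_rand_score
        cfg = GeneratorConfig(seed=seed, model="planted_partition",
                              n_blocks=4, block_size=25, p_in=0.3, p_out=0.01)
        net = gen_gene_network(cfg)
        labels = planted_labels(net)
        part = detect_communities(net, "fast_greedy", seed=seed)
        nodes = sorted(labels)
        ari = adjusted_rand_score([labels[n] for n in nodes],
                                  [part.assignment[n] for n in nodes])
        assert ari > 0.9


class TestPartitionQueries:
    def test_community_sizes_tallies(self, small_grn):
        part = detect_communities(small_grn)
        sizes = community_sizes(part, small_grn)
        assert sizes["n_nodes"].sum() == small_grn.n_nodes
        assert (sizes["n_nodes"] == sizes["n_mirnas"] + sizes["n_genes"]).all()
        # brute-force group-by oracle
        for row in sizes.itertuples():
            members = part.members(row.community)
            assert row.n_nodes == len(members)
            assert row.n_mirnas == len(members & small_grn.mirna_nodes)

    def test_community_sizes_rejects_foreign_partition(self, small_grn,
                                                       two_clique_grn):
        part = detect_communities(two_clique_grn)
        with pytest.raises(ConsistencyError):
            community_sizes(part, small_grn)

    def test_community_of_lookup_and_absent_marker(self, two_clique_grn):
        part = detect_communities(two_clique_grn)
        result = community_of(part, ["a1", "b1", "ghost"])
        assert result["a1"] == part.assignment["a1"]
        assert result["ghost"] is ABSENT

    def test_largest_community_extraction(self, two_clique_grn):
        part = detect_communities(two_clique_grn)
        cid = largest_community_id(part)
        sub = extract_community(two_clique_grn, part, cid)
        assert sub.n_nodes == 4 and sub.n_edges == 6   # a 4-clique

    def test_singleton_community_extracts_single_node(self):
        grn = MirnaGRN(gene_edges=[("a", "b")], gene_nodes=["c"])
        part = detect_communities(grn)
        lone = next(cid for cid in range(1, part.n_communities + 1)
                    if part.members(cid) == {"c"})
        sub = extract_community(grn, part, lone)
        assert sub.nodes == {"c"} and sub.n_edges == 0

    def test_unknown_community_id_rejected(self, two_clique_grn):
        part = detect_communities(two_clique_grn)
        with pytest.raises(ParameterError):
            extract_community(two_clique_grn, part, 99)

    @pytest.mark.parametrize("seed", range(3))
    def test_extraction_equals_brute_force_induction(self, seed):
        grn = random_grn(np.random.default_rng(seed))
        part = detect_communities(grn)
        cid = largest_community_id(part)
        sub = extract_community(grn, part, cid)
        members = part.members(cid)
        assert sub.gene_edges == {(a, b) for a, b in grn.gene_edges
                                  if a in members and b in members}
        assert sub.mirna_edges == {(m, t) for m, t in grn.mirna_edges
                                   if m in members and t in members}
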