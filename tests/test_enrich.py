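"""Consensus rules, network enrichment, DEG subnetworks, annotation joins."""
import numpy as np
import pytest

from mirgrn import (AnnotationRecord, GeneNetwork, MirnaGRN, MirnaTargetTable,
                    TargetRecord, combine_predicted, combine_validated,
                    deg_subnetwork, enrich_network, filter_extracellular,
                    join_annotations, summarize)
from mirgrn.errors import EvidenceClassError, ParameterError
from tests.conftest import random_grn


def table(pairs, source, evidence="predicted"):
    return MirnaTargetTable(TargetRecord(m, g, source, evidence)
                            for m, g in pairs)


def random_tables(rng, n_sources=4, n_mirnas=5, n_genes=8, p=0.3,
                  evidence="predicted"):
    out = []
    for s in range(n_sources):
        pairs = [(f"miR-{i}", f"g{j}") for i in range(n_mirnas)
                 for j in range(n_genes) if rng.random() < p]
        out.append(table(pairs, f"src{s}", evidence))
    return out


class TestCombineValidated:
    def test_union_of_pairs_with_provenance(self):
        t1 = table([("m1", "g1")], "dbA", "validated")
        t2 = table([("m1", "g2"), ("m1", "g1")], "dbB", "validated")
        combined = combine_validated([t1, t2])
        assert combined.pairs() == {("m1", "g1"), ("m1", "g2")}
        assert combined.sources_of("m1", "g1") == {"dbA", "dbB"}

    def test_idempotent_on_identical_tables(self):
        t = table([("m1", "g1"), ("m2", "g2")], "dbA", "validated")
        assert combine_validated([t, t]).pairs() == t.pairs()

    def test_wrong_evidence_class_raises(self):
        t = table([("m1", "g1")], "dbA", "predicted")
        with pytest.raises(EvidenceClassError):
            combine_validated([t])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_union(self, seed):
        tables = random_tables(np.random.default_rng(seed),
                               evidence="validated")
        combined = combine_validated(tables)
        assert combined.pairs() == set().union(*(t.pairs() for t in tables))


class TestCombinePredicted:
    def test_two_source_pair_kept_single_source_dropped(self):
        tables = [table([("m1", "g1"), ("m1", "g2")], "A"),
                  table([("m1", "g1")], "B")]
        consensus = combine_predicted(tables)
        assert consensus.pairs() == {("m1", "g1")}
        assert consensus.sources_of("m1", "g1") == {"A", "B"}

    def test_fewer_than_two_tables_is_an_arity_error(self):
        with pytest.raises(ParameterError):
            combine_predicted([table([("m1", "g1")], "A")])

    def test_mixed_evidence_rejected(self):
        tables = [table([("m1", "g1")], "A"),
                  table([("m1", "g1")], "B", "validated")]
        with pytest.raises(EvidenceClassError):
            combine_predicted(tables)

    def test_multiplicity_within_one_source_does_not_count(self):
        # the same source listed twice is still one supporting database
        t = table([("m1", "g1")], "A")
        assert combine_predicted([t, t]).pairs() == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_source_counting(self, seed):
        tables = random_tables(np.random.default_rng(seed))
        consensus = combine_predicted(tables)
        counts = {}
        for t in tables:
            for rec in t:
                counts.setdefault(rec.pair, set()).add(rec.source)
        expected = {p for p, srcs in counts.items() if len(srcs) >= 2}
        assert consensus.pairs() == expected
        # consensus never exceeds the union
        union = set().union(*(t.pairs() for t in tables))
        assert consensus.pairs() <= union

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_sources(self, seed):
        tables = random_tables(np.random.default_rng(seed), n_sources=4)
        before = combine_predicted(tables[:3]).pairs()
        after = combine_predicted(tables).pairs()
        assert before <= after


class TestEnrichNetwork:
    net = GeneNetwork.from_edges([("A", "B")])
    targets = table([("m1", "A"), ("m1", "C")], "dbA", "validated")

    def test_complete_mode_keeps_gene_layer_and_filters_targets(self):
        grn = enrich_network(self.net, self.targets, include_gene_edges=True)
        assert grn.gene_edges == {("A", "B")}
        assert grn.mirna_edges == {("m1", "A")}   # (m1, C) discarded

    def test_mirna_only_mode_restricts_to_targeted_genes(self):
        grn = enrich_network(self.net, self.targets, include_gene_edges=False)
        assert grn.nodes == {"m1", "A"}
        assert grn.gene_edges == set()
        assert grn.mirna_edges == {("m1", "A")}

    def test_empty_intersection_warns_and_yields_no_mirnas(self, caplog):
        lonely = table([("m1", "ZZZ")], "dbA", "validated")
        grn = enrich_network(self.net, lonely)
        assert grn.mirna_nodes == set()
        assert grn.gene_edges == {("A", "B")}

    @pytest.mark.parametrize("seed", range(5))
    def test_every_output_target_gene_is_a_network_node(self, seed):
        rng = np.random.default_rng(seed)
        net = GeneNetwork.from_edges(
            [(f"g{rng.integers(10)}", f"h{rng.integers(10)}")
             for _ in range(20)])
        targets = table([(f"miR-{i}", f"g{rng.integers(20)}")
                         for i in range(15)], "dbA", "validated")
        grn = enrich_network(net, targets)
        assert all(g in net.nodes for _, g in grn.mirna_edges)
        assert summarize(grn).n_genes <= net.n_nodes
        assert grn.gene_edges == net.edges

    def test_provenance_carries_all_supporting_sources(self):
        t1 = table([("m1", "A")], "dbA", "validated")
        t2 = table([("m1", "A")], "dbB", "validated")
        grn = enrich_network(self.net, combine_validated([t1, t2]))
        assert grn.sources_of("m1", "A") == ("dbA", "dbB")


class TestDegSubnetwork:
    grn = MirnaGRN(gene_edges=[("g1", "g2"), ("g2", "g3")],
                   mirna_edges=[("ma", "g1"), ("mb", "g3")])

    def test_keeps_deg_deg_edges_and_reattaches_mirnas(self):
        sub = deg_subnetwork(self.grn, {"g1", "g2"})
        assert sub.gene_nodes == {"g1", "g2"}
        assert sub.gene_edges == {("g1", "g2")}
        assert sub.mirna_edges == {("ma", "g1")}

    def test_degs_without_mutual_edges_give_empty_network(self):
        sub = deg_subnetwork(self.grn, {"g1", "g3"})
        assert sub.n_nodes == 0

    def test_empty_deg_set_gives_empty_network(self):
        assert deg_subnetwork(self.grn, set()).n_nodes == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_filter_and_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        grn = random_grn(rng)
        degs = {g for g in grn.gene_nodes if rng.random() < 0.5}
        sub = deg_subnetwork(grn, degs)
        expected_gene_edges = {(a, b) for a, b in grn.gene_edges
                               if a in degs and b in degs}
        surviving = {n for e in expected_gene_edges for n in e}
        expected_mirna_edges = {(m, t) for m, t in grn.mirna_edges
                                if t in surviving}
        assert sub.gene_edges == expected_gene_edges
        assert sub.mirna_edges == expected_mirna_edges
        assert sub.gene_nodes == surviving
        again = deg_subnetwork(sub, degs)
        assert again.gene_edges == sub.gene_edges
        assert again.mirna_edges == sub.mirna_edges


class TestAnnotationsAndFilters:
    targets = table([("hsa-miR-1", "TP53"), ("miR-2", "MYC")],
                    "dbA", "validated")

    def test_left_join_matches_on_normalized_id(self):
        ann = [AnnotationRecord("miR-1", "disease", "breast cancer")]
        joined = join_annotations(self.targets, ann, "disease")
        by_mirna = {a.record.mirna: a.annotations for a in joined}
        assert by_mirna["hsa-miR-1"][0].value == "breast cancer"
        assert by_mirna["miR-2"] == ()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            join_annotations(self.targets, [], "tissue")

    @pytest.mark.parametrize("seed", range(3))
    def test_join_equals_nested_loop(self, seed):
        rng = np.random.default_rng(seed)
        targets = table([(f"miR-{rng.integers(6)}", f"g{j}")
                         for j in range(10)], "dbA", "validated")
        ann = [AnnotationRecord(f"miR-{rng.integers(6)}", "drug", f"drug{k}")
               for k in range(8)]
        joined = join_annotations(targets, ann, "drug")
        for item in joined:
            expected = tuple(a for a in ann if a.mirna == item.record.mirna)
            assert item.annotations == expected

    def test_filter_extracellular_is_membership_filter(self):
        assert filter_extracellular(self.targets, set()).records == ()
        all_ids = self.targets.mirnas()
        assert filter_extracellular(self.targets, all_ids) == self.targets
        only = filter_extracellular(self.targets, {"miR-2"})
        assert only.pairs() == {("miR-2", "MYC")}
        assert only.sources == {"dbA"}
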