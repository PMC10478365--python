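"""Network construction, centralities against brute-force oracles, CTS, hubs."""

import networkx as nx
import pytest

from comorbid_rank.io_model import (
    AssociativeNetwork,
    DiseaseAssociation,
    DiseaseAssociationTable,
    InteractionType,
    NodeClass,
    NodeRecord,
    ValidationError,
)
from comorbid_rank.network_analysis import (
    CentralityRecord,
    CtsInput,
    HubCriteria,
    compute_centralities,
    cross_talk_specificity,
    detect_hubs,
    extract_regulatory_subnetwork,
    intersect_disease_networks,
    summarize_network,
)
from conftest import net_from_pairs
from oracles import brute_betweenness, brute_clustering


def _assoc(rows):
    return DiseaseAssociationTable(rows=[DiseaseAssociation(*r) for r in rows])


class TestIntersect:
    def test_shared_genes_induce_subgraph(self):
        assoc = _assoc(
            [("g1", "A", "network_db"), ("g2", "A", "network_db"),
             ("g3", "A", "network_db"), ("g2", "B", "network_db"),
             ("g3", "B", "network_db"), ("g4", "B", "network_db")]
        )
        global_net = net_from_pairs([("g2", "g3"), ("g3", "g4")])
        net = intersect_disease_networks(assoc, "A", "B", global_net)
        assert {n.id for n in net.nodes} == {"g2", "g3"}
        assert len(net.edges) == 1

    def test_disjoint_sets_warn_and_return_empty(self, caplog):
        assoc = _assoc([("g1", "A", "network_db"), ("g2", "B", "network_db")])
        with caplog.at_level("WARNING", logger="comorbid_rank"):
            net = intersect_disease_networks(assoc, "A", "B", net_from_pairs([("g1", "g2")]))
        assert len(net.nodes) == 0
        assert any("share no associated genes" in r.message for r in caplog.records)

    def test_sources_are_unioned(self):
        # in A via the network DB only, in B via GeneCards only: still shared
        assoc = _assoc(
            [("g1", "A", "network_db"), ("g1", "B", "genecards", 5.0),
             ("g2", "A", "network_db"), ("g2", "B", "network_db")]
        )
        net = intersect_disease_networks(assoc, "A", "B", net_from_pairs([("g1", "g2")]))
        assert {n.id for n in net.nodes} == {"g1", "g2"}

    def test_missing_disease_errors(self):
        assoc = _assoc([("g1", "A", "network_db")])
        with pytest.raises(ValidationError):
            intersect_disease_networks(assoc, "A", "Z", net_from_pairs([("g1", "g2")]))

    def test_idempotent(self):
        assoc = _assoc(
            [("g1", "A", "network_db"), ("g1", "B", "network_db"),
             ("g2", "A", "network_db"), ("g2", "B", "network_db")]
        )
        g = net_from_pairs([("g1", "g2")])
        once = intersect_disease_networks(assoc, "A", "B", g)
        twice = intersect_disease_networks(assoc, "A", "B", once)
        assert once.nodes == twice.nodes and once.edges == twice.edges


class TestRegulatorySubnetwork:
    def test_type_filter(self):
        net = AssociativeNetwork()
        net.add_edge("a", NodeClass.GENE, "b", NodeClass.GENE,
                     InteractionType.EXPRESSION_REGULATION)
        net.add_edge("b", NodeClass.GENE, "c", NodeClass.GENE,
                     InteractionType.ASSOCIATIVE)
        sub = extract_regulatory_subnetwork(net)
        assert len(sub.edges) == 1
        assert {n.id for n in sub.nodes} == {"a", "b"}  # isolated c dropped

    def test_only_associative_gives_empty(self):
        net = net_from_pairs([("a", "b")], itype=InteractionType.ASSOCIATIVE)
        sub = extract_regulatory_subnetwork(net)
        assert len(sub.edges) == 0 and len(sub.nodes) == 0

    def test_protein_to_gene_regulation_retained(self):
        net = AssociativeNetwork()
        net.add_edge("DRD2", NodeClass.PROTEIN, "SLC6A3", NodeClass.GENE,
                     InteractionType.EXPRESSION_REGULATION)
        sub = extract_regulatory_subnetwork(net)
        assert len(sub.edges) == 1

    def test_subgraph_containment(self, study):
        bundle, _, _ = study
        sub = extract_regulatory_subnetwork(bundle.network)
        assert sub.edges <= bundle.network.edges
        assert sub.nodes <= bundle.network.nodes


class TestSummarize:
    def test_counts_and_total(self):
        net = AssociativeNetwork()
        net.add_edge("a", NodeClass.GENE, "b", NodeClass.PROTEIN,
                     InteractionType.ASSOCIATIVE)
        net.add_edge("a", NodeClass.GENE, "c", NodeClass.GENE,
                     InteractionType.DOWNREGULATION)
        s = summarize_network(net)
        assert s.total_edges == 2 == sum(s.per_type_edge_counts.values())
        assert s.n_gene_nodes == 2 and s.n_protein_nodes == 1

    def test_empty_network_all_zero(self):
        s = summarize_network(AssociativeNetwork())
        assert s.total_edges == 0 and s.n_nodes == 0


class TestCentralities:
    @staticmethod
    def _records(pairs):
        return {r.entity: r for r in compute_centralities(net_from_pairs(pairs))}

    def test_path_graph(self):
        rec = self._records([("A", "B"), ("B", "C")])
        assert rec["B"].bc == pytest.approx(1.0)
        assert rec["A"].bc == rec["C"].bc == 0.0
        assert rec["B"].cc == 0.0
        assert rec["B"].dc == pytest.approx(1.0)

    def test_triangle(self):
        rec = self._records([("A", "B"), ("B", "C"), ("A", "C")])
        for r in rec.values():
            assert r.cc == pytest.approx(1.0)
            assert r.bc == pytest.approx(0.0)

    def test_star(self):
        rec = self._records([("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3")])
        assert rec["HUB"].bc == pytest.approx(1.0)
        assert rec["HUB"].cc == 0.0
        assert rec["L1"].dc == pytest.approx(1 / 3)

    def test_single_node_errors(self):
        net = AssociativeNetwork()
        net.add_node(NodeRecord("A", NodeClass.GENE))
        with pytest.raises(ValidationError):
            compute_centralities(net)

    def test_gene_and_protein_nodes_merge_into_one_entity(self):
        net = AssociativeNetwork()
        net.add_edge("A", NodeClass.GENE, "B", NodeClass.GENE,
                     InteractionType.ASSOCIATIVE)
        net.add_edge("a", NodeClass.PROTEIN, "C", NodeClass.PROTEIN,
                     InteractionType.PROTEIN_PROTEIN)
        rec = {r.entity: r for r in compute_centralities(net)}
        assert len(rec) == 3
        assert rec["A"].degree_raw == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(4 + 3 * seed, 0.25, seed=seed)
        mapping = {i: f"N{i:02d}" for i in g.nodes}
        pairs = [(mapping[u], mapping[v]) for u, v in g.edges]
        net = net_from_pairs(pairs)
        for n in g.nodes:  # keep isolated nodes too
            net.add_node(NodeRecord(mapping[n], NodeClass.GENE))
        records = compute_centralities(net)
        nodes = [r.entity for r in records]
        bc = brute_betweenness(nodes, pairs)
        cc = brute_clustering(nodes, pairs)
        for r in records:
            assert r.bc == pytest.approx(bc[r.entity], abs=1e-9)
            assert r.cc == pytest.approx(cc[r.entity], abs=1e-9)

    def test_adding_edge_never_decreases_degree(self):
        pairs = [("A", "B"), ("B", "C"), ("C", "D")]
        before = {r.entity: r for r in compute_centralities(net_from_pairs(pairs))}
        after = {
            r.entity: r
            for r in compute_centralities(net_from_pairs(pairs + [("A", "C")]))
        }
        for entity, rec in before.items():
            assert after[entity].degree_raw >= rec.degree_raw
            assert after[entity].dc >= rec.dc


class TestCts:
    def test_formula(self):
        assert cross_talk_specificity(CtsInput(k_i=5, m_i=50)) == pytest.approx(0.1)

    def test_identity_case(self):
        assert cross_talk_specificity(CtsInput(k_i=7, m_i=7)) == 1.0

    def test_zero_global_links_errors(self):
        with pytest.raises(ValidationError):
            cross_talk_specificity(CtsInput(k_i=0, m_i=0))

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValidationError):
            cross_talk_specificity(CtsInput(k_i=8, m_i=7))


class TestHubs:
    @staticmethod
    def _rec(bc, cc, degree):
        return CentralityRecord(entity="G", dc=0.5, bc=bc, cc=cc, degree_raw=degree)

    @pytest.mark.parametrize(
        "bc,cc,degree,is_hub",
        [
            (0.006, 0.25, 41, True),   # all three cutoffs passed
            (0.005, 0.2, 41, True),    # bc/cc boundaries are inclusive
            (0.006, 0.25, 40, False),  # degree cutoff is strict
            (0.004, 0.9, 100, False),  # bc below cutoff
        ],
    )
    def test_cutoff_boundaries(self, bc, cc, degree, is_hub):
        hubs = detect_hubs([self._rec(bc, cc, degree)], HubCriteria())
        assert ("G" in hubs) is is_hub
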