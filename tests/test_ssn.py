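"""SSN construction, cluster analysis, label derivation and export."""

import networkx as nx
import pytest

from ssnplm import (
    Cluster,
    ClusterPartition,
    ProteinSequence,
    SSNGraph,
    SSNParams,
    SequenceSet,
    build_ssn,
    export_graph,
    find_clusters,
    top_k_labels,
)

from conftest import random_protein
from _oracles import oracle_align


def graph_from_edges(n_nodes, edges, threshold=0.4):
    nodes = [str(i) for i in range(1, n_nodes + 1)]
    e = [(str(a), str(b), 1.0) for a, b in edges]
    return SSNGraph(nodes, e, SSNParams(identity_threshold=threshold))


class TestFindClusters:
    def test_component_enumeration(self):
        part = find_clusters(graph_from_edges(7, [(1, 2), (2, 3), (4, 5)]))
        assert [c.members for c in part.clusters] == [("1", "2", "3"), ("4", "5")]
        assert [c.cluster_id for c in part.clusters] == [1, 2]
        assert part.singletons == ["6", "7"]

    def test_complete_component_has_unit_convergence(self):
        edges = [(a, b) for a in range(1, 5) for b in range(a + 1, 5)]
        part = find_clusters(graph_from_edges(4, edges))
        assert len(part.clusters) == 1
        assert part.clusters[0].convergence_ratio == 1.0

    def test_path_graph_convergence_ratio(self):
        part = find_clusters(graph_from_edges(3, [(1, 2), (2, 3)]))
        assert part.clusters[0].convergence_ratio == pytest.approx(2 / 3)

    def test_partition_covers_all_nodes(self):
        part = find_clusters(graph_from_edges(9, [(1, 2), (3, 4), (4, 5)]))
        assert part.n_nodes == 9

    def test_equal_size_ties_break_by_smallest_member(self):
        part = find_clusters(graph_from_edges(4, [(3, 4), (1, 2)]))
        assert part.clusters[0].members == ("1", "2")
        assert part.clusters[1].members == ("3", "4")

    def test_cluster_ids_stable_under_node_permutation(self, rng):
        edges = [(1, 2), (2, 3), (5, 6), (7, 8), (8, 9), (9, 7)]
        base = find_clusters(graph_from_edges(9, edges))
        g = graph_from_edges(9, edges)
        perm = list(g.nodes)
        rng.shuffle(perm)
        shuffled = SSNGraph(perm, g.edges[::-1], g.params)
        again = find_clusters(shuffled)
        assert [c.members for c in base.clusters] == [c.members for c in again.clusters]


class TestBuildSSN:
    def test_identical_pair_forms_edge(self):
        seqs = SequenceSet(
            [ProteinSequence("a", "ACDEFGHIKLMN"), ProteinSequence("b", "ACDEFGHIKLMN")]
        )
        g = build_ssn(seqs)
        assert g.n_edges == 1
        assert g.edges[0][2] == 1.0

    def test_unrelated_pair_has_no_edge(self, rng):
        a = random_protein(rng, 50, "a")
        b = random_protein(rng, 50, "b")
        g = build_ssn(SequenceSet([a, b]), SSNParams(identity_threshold=0.40))
        assert g.n_edges == 0
        # oracle confirms: no optimal local alignment reaches 40% of 50 sites
        _, pairs = oracle_align(a.residues, b.residues, mode="local")
        assert all(ident / 50 < 0.40 for ident, _ in pairs)

    def test_family_structure_recovered(self):
        """Three families at ~0.7 within-family identity: every intra-family
        pair is an edge, no inter-family edge."""
        from ssnplm import FamilyConfig, generate_families

        corpus = generate_families(
            FamilyConfig(n_families=3, members_per_family=4, length=100, p_sub=0.16, seed=3)
        )
        g = build_ssn(corpus.sequences, SSNParams(identity_threshold=0.40))
        fam = corpus.truth
        for a, b, ident in g.edges:
            assert fam[a] == fam[b], f"inter-family edge {a}-{b} at {ident:.2f}"
        expected = 3 * (4 * 3 // 2)
        assert g.n_edges == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_ssn(SequenceSet([]))


class TestTopKLabels:
    def make_partition(self, sizes, n_singletons=0):
        clusters = []
        nid = 0
        for rank, size in enumerate(sizes, 1):
            members = tuple(f"n{nid + i}" for i in range(size))
            nid += size
            clusters.append(Cluster(rank, members, size * (size - 1) // 2))
        singles = [f"x{i}" for i in range(n_singletons)]
        return ClusterPartition(clusters, singles)

    def test_top_two_of_three_clusters(self):
        part = self.make_partition([5, 3, 2], n_singletons=2)
        labels = top_k_labels(part, 2)
        assert len(labels) == 8
        assert set(labels.labels.values()) == {1, 2}

    def test_k_exceeding_cluster_count_labels_all_clusters(self):
        part = self.make_partition([4, 3], n_singletons=3)
        labels = top_k_labels(part, 10)
        assert len(labels) == 7
        assert not any(sid.startswith("x") for sid in labels.labels)

    def test_k45_label_alphabet(self):
        part = self.make_partition([3] * 60)
        labels = top_k_labels(part, 45)
        assert set(labels.labels.values()) == set(range(1, 46))


class TestExportGraph:
    def test_graphml_round_trip(self, tmp_path):
        g = graph_from_edges(5, [(1, 2), (2, 3)])
        part = find_clusters(g)
        p = tmp_path / "net.graphml"
        export_graph(g, part, p, format="graphml")
        back = nx.read_graphml(p)
        assert set(back.nodes) == set(g.nodes)
        assert back.number_of_edges() == g.n_edges
        assert back.nodes["1"]["cluster"] == "1"
        assert back.nodes["4"]["cluster"] == "singleton"
        assert back.edges["1", "2"]["identity"] == 1.0

    def test_edgeless_graph_exports_nodes_only(self, tmp_path):
        g = graph_from_edges(3, [])
        part = find_clusters(g)
        p = tmp_path / "net.graphml"
        export_graph(g, part, p, format="graphml")
        back = nx.read_graphml(p)
        assert len(back.nodes) == 3 and back.number_of_edges() == 0

    def test_edge_tsv_row_count(self, tmp_path):
        g = graph_from_edges(3, [(1, 2), (2, 3)])
        part = find_clusters(g)
        p = tmp_path / "edges.tsv"
        export_graph(g, part, p, format="edge-tsv")
        lines = p.read_text().strip().split("\n")
        assert lines[0] == "source\ttarget\tidentity"
        assert len(lines) == 3
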