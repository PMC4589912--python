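from itertools import combinations, permutations

import numpy as np
import pytest

import sepsisbn as s
from sepsisbn.consensus import (
    build_consensus,
    detect_v_structures,
    detect_y_structures,
    markov_equivalent,
    v_structure_set,
)
from sepsisbn.dag import Dag
from sepsisbn.score import ScoredNetwork
from sepsisbn.search import enumerate_dags


def nets(*edge_lists, nodes=("A", "B", "C"), scores=None):
    scores = scores or [0.0] * len(edge_lists)
    return [
        ScoredNetwork(Dag(nodes, edges), score)
        for edges, score in zip(edge_lists, scores)
    ]


class TestBuildConsensus:
    def test_opposing_orientations_become_undirected(self):
        c = build_consensus(nets([("A", "B")], [("B", "A")]))
        assert c.undirected == {frozenset({"A", "B"})}
        assert c.directed == set()

    def test_unanimous_direction_stays_directed(self):
        c = build_consensus(nets([("A", "B")], [("A", "B")]))
        assert c.directed == {("A", "B")}
        assert c.undirected == set()

    def test_single_network_all_edges_directed(self):
        c = build_consensus(nets([("A", "B"), ("B", "C")]))
        assert c.directed == {("A", "B"), ("B", "C")}
        assert c.undirected == set()

    def test_partial_adjacency_excluded_with_support(self):
        c = build_consensus(nets([("A", "B"), ("B", "C")], [("A", "B")]))
        assert c.directed == {("A", "B")}
        assert c.undirected == set()
        assert c.excluded == {frozenset({"B", "C"}): 1}

    def test_score_filter_drops_suboptimal_networks(self):
        c = build_consensus(
            nets([("A", "B")], [("B", "A")], scores=[0.0, -5.0]),
            score_tolerance=1e-9,
        )
        # only the top network is kept, so its orientation is unanimous
        assert c.directed == {("A", "B")}
        assert c.n_networks == 1

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            build_consensus(
                [
                    ScoredNetwork(Dag(("A", "B")), 0.0),
                    ScoredNetwork(Dag(("A", "C")), 0.0),
                ]
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])

    def test_markov_equivalent_top_set_yields_shared_skeleton(self):
        # the full equivalence class of A-B-C chain: compelled edges vanish
        class_members = nets(
            [("A", "B"), ("B", "C")],
            [("B", "A"), ("B", "C")],
            [("C", "B"), ("B", "A")],
        )
        c = build_consensus(class_members)
        assert c.directed == set()
        assert c.undirected == {frozenset({"A", "B"}), frozenset({"B", "C"})}


def brute_force_colliders(dag: Dag):
    out = []
    adj = dag.skeleton()
    for a, b, c in permutations(dag.nodes, 3):
        if a < b and dag.has_edge(a, c) and dag.has_edge(b, c) \
                and frozenset((a, b)) not in adj:
            out.append((a, b, c))
    return sorted(out)


class TestMotifDetection:
    def test_chain_has_no_collider(self):
        dag = Dag(("A", "B", "C"), [("A", "B"), ("B", "C")])
        assert detect_v_structures(dag).colliders == []

    def test_clp_lung_insult_collider(self):
        dag = Dag(
            ("CLP", "LungInsult", "NE", "EO"),
            [("CLP", "NE"), ("LungInsult", "NE"), ("NE", "EO")],
        )
        report = detect_y_structures(dag)
        assert report.colliders == [("CLP", "LungInsult", "NE")]
        assert report.y_structures == [("CLP", "LungInsult", "NE", "EO")]

    def test_adjacent_parents_not_a_collider(self):
        dag = Dag(("A", "B", "C"), [("A", "C"), ("B", "C"), ("A", "B")])
        assert detect_v_structures(dag).colliders == []

    def test_collider_without_child_has_no_y(self):
        dag = Dag(("A", "B", "C"), [("A", "C"), ("B", "C")])
        report = detect_y_structures(dag)
        assert report.colliders == [("A", "B", "C")]
        assert report.y_structures == []

    def test_agrees_with_brute_force_on_all_three_node_dags(self):
        nodes = ("A", "B", "C")
        for parents in enumerate_dags(nodes):
            dag = Dag(nodes, [(p, c) for c, ps in parents.items() for p in ps])
            assert detect_v_structures(dag).colliders == brute_force_colliders(dag)

    def test_y_count_matches_collider_outdegree_on_random_dags(self):
        rng = np.random.default_rng(4)
        nodes = tuple("ABCDEF")
        for _ in range(50):
            dag = Dag(nodes)
            for u, v in permutations(nodes, 2):
                if rng.random() < 0.25:
                    try:
                        dag.add_edge(u, v)
                    except s.CycleError:
                        pass
            report = detect_y_structures(dag)
            expected = sum(
                len(dag.children(c)) for _, _, c in report.colliders
            )
            assert len(report.y_structures) == expected

    def test_consensus_motifs_use_directed_edges_only(self):
        c = build_consensus(
            nets(
                [("A", "C"), ("B", "C"), ("C", "D")],
                [("A", "C"), ("B", "C"), ("D", "C")],
                nodes=("A", "B", "C", "D"),
            )
        )
        report = detect_y_structures(c)
        assert report.colliders == [("A", "B", "C")]
        assert report.y_structures == []  # C-D is undirected


class TestMarkovEquivalence:
    def test_chains_and_fork_equivalent(self):
        nodes = ("A", "B", "C")
        d1 = Dag(nodes, [("A", "B"), ("B", "C")])
        d2 = Dag(nodes, [("C", "B"), ("B", "A")])
        d3 = Dag(nodes, [("B", "A"), ("B", "C")])
        assert markov_equivalent(d1, d2)
        assert markov_equivalent(d1, d3)
        assert markov_equivalent(d2, d3)

    def test_collider_not_equivalent_to_chain(self):
        nodes = ("A", "B", "C")
        collider = Dag(nodes, [("A", "C"), ("B", "C")])
        chain = Dag(nodes, [("A", "C"), ("C", "B")])
        assert not markov_equivalent(collider, chain)

    def test_three_node_dags_partition_into_eleven_classes(self):
        nodes = ("A", "B", "C")
        dags = [
            Dag(nodes, [(p, c) for c, ps in parents.items() for p in ps])
            for parents in enumerate_dags(nodes)
        ]
        classes: list[Dag] = []
        for dag in dags:
            if not any(markov_equivalent(dag, rep) for rep in classes):
                classes.append(dag)
        assert len(dags) == 25
        assert len(classes) == 11

    def test_mismatched_nodes_rejected(self):
        with pytest.raises(ValueError):
            markov_equivalent(Dag(("A", "B")), Dag(("A", "C")))


class TestConsensusIO:
    def test_edge_list_roundtrip(self, tmp_path):
        c = build_consensus(
            nets([("A", "B"), ("B", "C")], [("A", "B"), ("C", "B")])
        )
        path = tmp_path / "consensus.tsv"
        c.write_edge_list(path)
        back = s.ConsensusNetwork.read_edge_list(path)
        assert back.directed == c.directed
        assert back.undirected == c.undirected
        assert back.nodes == c.nodes

    def test_graphml_and_dot_exports(self, tmp_path):
        import networkx as nx

        c = build_consensus(nets([("A", "B")], [("B", "A")]))
        c.write_graphml(tmp_path / "c.graphml")
        g = nx.read_graphml(tmp_path / "c.graphml")
        assert g.number_of_edges() == 1
        dot = c.to_dot()
        assert "dir=none" in dot
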