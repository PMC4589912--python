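"""Consensus networks and the interpreted graph motifs.

From the set of top-scoring networks a consensus graph is built by
unanimity: an adjacency {u, v} enters the consensus only if it is present
(in some orientation) in every kept network; it is drawn as a directed
edge u -> v when that orientation holds in all of them, and as an
undirected edge when it appears at least once in the opposing direction.

Motifs:

* a *collider* (fork-like "V") is a triple a -> c <- b with a and b
  non-adjacent — the orientation pattern that is identifiable from
  observational data and that flags c as co-regulated by two factors;
* a *Y structure* extends a collider by one directed edge c -> d,
  suggesting a causal chain through c.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .dag import Dag
from .score import ScoredNetwork

CONSENSUS_TOL = 1e-9


@dataclass
class ConsensusNetwork:
    """Unanimity consensus over a set of equally top-scoring networks."""

    nodes: tuple[str, ...]
    directed: set[tuple[str, str]]
    undirected: set[frozenset[str]]
    #: adjacency -> number of kept networks containing it (consensus edges
    #: have full support by construction)
    support: dict[frozenset[str], int] = field(default_factory=dict)
    #: adjacencies seen in some but not all kept networks (excluded)
    excluded: dict[frozenset[str], int] = field(default_factory=dict)
    n_networks: int = 0
    top_score: float = 0.0

    def adjacencies(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def adjacent(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.adjacencies()

    def directed_parents(self, node: str) -> set[str]:
        return {u for u, v in self.directed if v == node}

    def directed_children(self, node: str) -> set[str]:
        return {v for u, v in self.directed if u == node}

    # -- io ---------------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in sorted(self.directed):
            g.add_edge(u, v, directed=True,
                       support=self.support.get(frozenset((u, v)), self.n_networks))
        for e in sorted(self.undirected, key=sorted):
            u, v = sorted(e)
            g.add_edge(u, v, directed=False,
                       support=self.support.get(e, self.n_networks))
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def to_dot(self) -> str:
        lines = ["digraph consensus {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.directed):
            lines.append(f'  "{u}" -> "{v}";')
        for e in sorted(self.undirected, key=sorted):
            u, v = sorted(e)
            lines.append(f'  "{u}" -> "{v}" [dir=none];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def write_edge_list(self, path: str | Path) -> None:
        lines = [f"# nodes: {','.join(self.nodes)}"]
        for u, v in sorted(self.directed):
            lines.append(f"{u}\t{v}\tdirected")
        for e in sorted(self.undirected, key=sorted):
            u, v = sorted(e)
            lines.append(f"{u}\t{v}\tundirected")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_edge_list(cls, path: str | Path) -> "ConsensusNetwork":
        nodes: tuple[str, ...] = ()
        directed: set[tuple[str, str]] = set()
        undirected: set[frozenset[str]] = set()
        for line in Path(path).read_text().strip().splitlines():
            if line.startswith("# nodes:"):
                nodes = tuple(n for n in line.split(":", 1)[1].strip().split(",") if n)
            elif line.strip() and not line.startswith("#"):
                u, v, kind = line.split("\t")
                if kind == "directed":
                    directed.add((u, v))
                else:
                    undirected.add(frozenset((u, v)))
        return cls(nodes=nodes, directed=directed, undirected=undirected)


@dataclass
class MotifReport:
    """Colliders (V motifs) and Y structures found in a graph."""

    colliders: list[tuple[str, str, str]] = field(default_factory=list)
    y_structures: list[tuple[str, str, str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "colliders": [list(c) for c in self.colliders],
                "y_structures": [list(y) for y in self.y_structures],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def build_consensus(
    networks: list[ScoredNetwork], score_tolerance: float = CONSENSUS_TOL
) -> ConsensusNetwork:
    """Build the unanimity consensus of the top-scoring networks.

    Networks scoring within ``score_tolerance`` of the maximum are kept;
    the rest are discarded before the edge rules apply.
    """
    if not networks:
        raise ValueError("need at least one scored network")
    node_set = set(networks[0].dag.nodes)
    for sn in networks[1:]:
        if set(sn.dag.nodes) != node_set:
            raise ValueError("networks must share one node set")

    top = max(sn.log_posterior for sn in networks)
    kept = [sn for sn in networks if sn.log_posterior >= top - score_tolerance]

    adj_count: dict[frozenset[str], int] = {}
    dir_count: dict[tuple[str, str], int] = {}
    for sn in kept:
        for u, v in sn.dag.edges():
            adj_count[frozenset((u, v))] = adj_count.get(frozenset((u, v)), 0) + 1
            dir_count[(u, v)] = dir_count.get((u, v), 0) + 1

    n = len(kept)
    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset[str]] = set()
    support: dict[frozenset[str], int] = {}
    excluded: dict[frozenset[str], int] = {}
    for adj, count in adj_count.items():
        if count < n:
            excluded[adj] = count
            continue
        support[adj] = count
        u, v = sorted(adj)
        if dir_count.get((u, v), 0) == n:
            directed.add((u, v))
        elif dir_count.get((v, u), 0) == n:
            directed.add((v, u))
        else:
            undirected.add(adj)

    return ConsensusNetwork(
        nodes=networks[0].dag.nodes,
        directed=directed,
        undirected=undirected,
        support=support,
        excluded=excluded,
        n_networks=n,
        top_score=top,
    )


def _directed_view(graph: Dag | ConsensusNetwork):
    """(nodes, parents-of, adjacency-test) over the directed part of a graph."""
    if isinstance(graph, Dag):
        adjacencies = graph.skeleton()
        return (
            graph.nodes,
            graph.parents,
            graph.children,
            lambda a, b: frozenset((a, b)) in adjacencies,
        )
    return (
        graph.nodes,
        graph.directed_parents,
        graph.directed_children,
        graph.adjacent,
    )


def detect_v_structures(graph: Dag | ConsensusNetwork) -> MotifReport:
    """Find all colliders a -> c <- b with a, b non-adjacent.

    Reported triples are normalized with the parent pair sorted; in a
    consensus network only directed edges orient a collider, and the
    adjacency test includes undirected edges.
    """
    nodes, parents_of, _children_of, adjacent = _directed_view(graph)
    colliders: list[tuple[str, str, str]] = []
    for c in nodes:
        ps = sorted(parents_of(c))
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                a, b = ps[i], ps[j]
                if not adjacent(a, b):
                    colliders.append((a, b, c))
    colliders.sort()
    return MotifReport(colliders=colliders)


def detect_y_structures(graph: Dag | ConsensusNetwork) -> MotifReport:
    """Find Y structures: a collider (a, b, c) plus a directed edge c -> d."""
    report = detect_v_structures(graph)
    nodes, _parents_of, children_of, _adjacent = _directed_view(graph)
    ys: list[tuple[str, str, str, str]] = []
    for a, b, c in report.colliders:
        for d in sorted(children_of(c)):
            ys.append((a, b, c, d))
    ys.sort()
    return MotifReport(colliders=report.colliders, y_structures=ys)


def v_structure_set(dag: Dag) -> set[tuple[str, str, str]]:
    """The v-structures of a DAG as normalized (parentA, parentB, child) triples."""
    return set(detect_v_structures(dag).colliders)


def markov_equivalent(d1: Dag, d2: Dag) -> bool:
    """True iff two DAGs share skeleton and v-structures (same Markov class)."""
    if set(d1.nodes) != set(d2.nodes):
        raise ValueError("DAGs must share one node set")
    return d1.skeleton() == d2.skeleton() and v_structure_set(d1) == v_structure_set(d2)
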