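"""Directed acyclic graphs over named discrete variables.

A light mutable DAG container used by the scorer and the annealing search.
Acyclicity is enforced on every mutation.  Import/export: tab-separated
edge lists, DOT, and GraphML (via networkx).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx


class CycleError(ValueError):
    """Raised when a mutation would create a directed cycle."""


class Dag:
    """A DAG with a fixed node set and mutable edges."""

    __slots__ = ("nodes", "_parents", "_children")

    def __init__(self, nodes: Iterable[str],
                 edges: Iterable[tuple[str, str]] = ()) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- queries ----------------------------------------------------------

    def parents(self, node: str) -> frozenset[str]:
        return frozenset(self._parents[node])

    def children(self, node: str) -> frozenset[str]:
        return frozenset(self._children[node])

    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for v, ps in self._parents.items() for u in ps}

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._children.get(u, ())

    def has_path(self, src: str, dst: str) -> bool:
        """True iff a directed path src -> ... -> dst exists (src == dst counts)."""
        if src == dst:
            return True
        stack = [src]
        seen = {src}
        while stack:
            for child in self._children[stack.pop()]:
                if child == dst:
                    return True
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return False

    def n_edges(self) -> int:
        return sum(len(ps) for ps in self._parents.values())

    # -- mutation ---------------------------------------------------------

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if u not in self._parents or v not in self._parents:
            raise KeyError(f"unknown node in edge ({u!r}, {v!r})")
        if self.has_edge(u, v):
            return
        if self.has_path(v, u):
            raise CycleError(f"edge {u!r}->{v!r} would create a cycle")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.has_edge(u, v):
            raise KeyError(f"edge {u!r}->{v!r} not present")
        self._parents[v].discard(u)
        self._children[u].discard(v)

    def reverse_edge(self, u: str, v: str) -> None:
        self.remove_edge(u, v)
        try:
            self.add_edge(v, u)
        except CycleError:
            self.add_edge(u, v)  # restore
            raise

    def copy(self) -> "Dag":
        out = Dag(self.nodes)
        for v, ps in self._parents.items():
            out._parents[v] = set(ps)
        for u, cs in self._children.items():
            out._children[u] = set(cs)
        return out

    # -- structure --------------------------------------------------------

    def topological_order(self) -> list[str]:
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        ready = [n for n in self.nodes if indeg[n] == 0]
        order: list[str] = []
        while ready:
            n = ready.pop()
            order.append(n)
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise CycleError("graph contains a cycle")
        return order

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.edges()}

    def edge_key(self) -> frozenset[tuple[str, str]]:
        """Hashable identity of the edge set (for dedup across searches)."""
        return frozenset(self.edges())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edge_key() == other.edge_key()

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.edge_key()))

    def __repr__(self) -> str:
        return f"Dag(nodes={len(self.nodes)}, edges={sorted(self.edges())})"

    # -- io ---------------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges()))
        return g

    def write_edge_list(self, path: str | Path) -> None:
        lines = [f"# nodes: {','.join(self.nodes)}"]
        lines += [f"{u}\t{v}" for u, v in sorted(self.edges())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_edge_list(cls, path: str | Path) -> "Dag":
        text = Path(path).read_text().strip().splitlines()
        nodes: tuple[str, ...] = ()
        edges = []
        for line in text:
            if line.startswith("# nodes:"):
                nodes = tuple(n for n in line.split(":", 1)[1].strip().split(",") if n)
            elif line.strip() and not line.startswith("#"):
                u, v = line.split("\t")
                edges.append((u, v))
        if not nodes:
            nodes = tuple(sorted({n for e in edges for n in e}))
        return cls(nodes, edges)

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.edges()):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def is_acyclic(edges: Iterable[tuple[str, str]],
               nodes: Iterable[str] | None = None) -> bool:
    """True iff the directed graph given by ``edges`` admits a topological order."""
    edges = list(edges)
    if nodes is None:
        nodes = {n for e in edges for n in e}
    try:
        d = Dag(nodes)
        for u, v in edges:
            d.add_edge(u, v)
    except CycleError:
        return False
    return True
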