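"""Model/Results interface over the discretize -> search -> consensus chain.

``CompartmentBNModel`` is built from a sample table (animals x variables);
``fit()`` runs the restarted annealing search and returns ``BNResults``
carrying the scored networks, the consensus graph, the motif report, and a
text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .consensus import (
    CONSENSUS_TOL,
    ConsensusNetwork,
    MotifReport,
    build_consensus,
    detect_y_structures,
)
from .design import CONDITION_CARDINALITIES
from .discretize import DiscreteTable, DiscretizationScheme, discretize
from .generate import SampleTable
from .score import ScoredNetwork
from .search import SearchConfig, anneal_search


class CompartmentBNModel:
    """Discrete Bayesian-network structure model for one sample table.

    Parameters
    ----------
    data : continuous sample table; condition columns (any column with a
        declared condition cardinality, or the names in ``condition_vars``)
        pass through discretization untouched.
    policy : discretization policy ("tertiles" or "manual").
    manual_edges : per-variable (cut1, cut2) when policy is "manual".
    ess : BDeu equivalent sample size.
    max_parents : parent-count cap during search.
    """

    def __init__(
        self,
        data: pd.DataFrame | SampleTable,
        condition_vars: tuple[str, ...] | None = None,
        policy: str = "tertiles",
        manual_edges: dict[str, tuple[float, float]] | None = None,
        ess: float = 1.0,
        max_parents: int = 5,
    ) -> None:
        if isinstance(data, SampleTable):
            self.compartment: str | None = data.compartment
            data = data.data
        else:
            self.compartment = None
        self.data = data
        self.ess = ess
        self.max_parents = max_parents
        self.discrete, self.scheme = discretize(
            data, policy=policy, manual_edges=manual_edges,
            condition_vars=condition_vars,
        )

    @classmethod
    def from_sample_table(cls, table: SampleTable, **kwargs) -> "CompartmentBNModel":
        return cls(table, **kwargs)

    def fit(
        self,
        n_restarts: int = 20,
        proposals_per_restart: int = 100_000,
        seed: int = 0,
        consensus_tolerance: float = CONSENSUS_TOL,
        **search_kwargs,
    ) -> "BNResults":
        """Run the annealing search and build the consensus network."""
        config = SearchConfig(
            ess=self.ess,
            max_parents=self.max_parents,
            n_restarts=n_restarts,
            proposals_per_restart=proposals_per_restart,
            seed=seed,
            **search_kwargs,
        )
        networks = anneal_search(self.discrete, config)
        consensus = build_consensus(networks, consensus_tolerance)
        return BNResults(self, config, networks, consensus)


@dataclass
class BNResults:
    """Fitted structure-learning results for one table."""

    model: CompartmentBNModel
    config: SearchConfig
    networks: list[ScoredNetwork]
    consensus: ConsensusNetwork
    _motifs: MotifReport | None = field(default=None, repr=False)

    @property
    def top_score(self) -> float:
        return self.networks[0].log_posterior

    @property
    def n_top_networks(self) -> int:
        return self.consensus.n_networks

    def motifs(self) -> MotifReport:
        """Colliders and Y structures of the consensus network."""
        if self._motifs is None:
            self._motifs = detect_y_structures(self.consensus)
        return self._motifs

    def summary(self) -> str:
        m = self.motifs()
        c = self.consensus
        lines = [
            "Discrete Bayesian network structure results",
            "===========================================",
            f"compartment:        {self.model.compartment or '-'}",
            f"observations:       {len(self.model.data)}",
            f"variables:          {len(c.nodes)}",
            f"ESS / max parents:  {self.config.ess} / {self.config.max_parents}",
            f"restarts x props:   {self.config.n_restarts} x "
            f"{self.config.proposals_per_restart}",
            f"top log posterior:  {self.top_score:.4f}",
            f"networks at top:    {self.n_top_networks}",
            f"consensus edges:    {len(c.directed)} directed, "
            f"{len(c.undirected)} undirected",
            "",
            "Directed edges:",
        ]
        lines += [f"  {u} -> {v}" for u, v in sorted(c.directed)] or ["  (none)"]
        lines.append("Undirected edges:")
        lines += [
            f"  {a} -- {b}" for a, b in (sorted(e) for e in
                                         sorted(c.undirected, key=sorted))
        ] or ["  (none)"]
        lines.append("Colliders (V):")
        lines += [f"  {a} -> {c_} <- {b}" for a, b, c_ in m.colliders] or ["  (none)"]
        lines.append("Y structures:")
        lines += [
            f"  ({a}, {b}) -> {c_} -> {d}" for a, b, c_, d in m.y_structures
        ] or ["  (none)"]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Draw the consensus graph (directed edges with arrowheads)."""
        import matplotlib.pyplot as plt

        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 8))
        g = self.consensus.to_networkx()
        pos = nx.spring_layout(g, seed=0)
        nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#c6dbef")
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
        directed = [(u, v) for u, v, d in g.edges(data=True) if d["directed"]]
        undirected = [(u, v) for u, v, d in g.edges(data=True) if not d["directed"]]
        nx.draw_networkx_edges(g, pos, edgelist=directed, ax=ax,
                               arrows=True, arrowstyle="-|>")
        nx.draw_networkx_edges(g, pos, edgelist=undirected, ax=ax, arrows=False)
        ax.set_axis_off()
        return ax
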