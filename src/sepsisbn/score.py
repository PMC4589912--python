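"""Bayesian-Dirichlet (BDeu) scoring of discrete Bayesian networks.

The score of a DAG G for a discrete data set D is the log marginal
likelihood under Dirichlet priors on every conditional probability table,
with the uniform ("u") hyperparameter assignment

    alpha_ijk = ESS / (q_i * r_i),        alpha_ij = ESS / q_i,

where r_i is the state count of variable i, q_i the number of joint parent
configurations, and ESS the equivalent sample size.  The family term for
child i with counts N_ijk (parent configuration j, child state k) is

    sum_j [ lnGamma(alpha_ij) - lnGamma(alpha_ij + N_ij) ]
  + sum_jk [ lnGamma(alpha_ijk + N_ijk) - lnGamma(alpha_ijk) ]

and the network score is the sum of family terms (decomposability).  With
no structural prior the log posterior used for ranking equals this score
up to an additive constant.  BDeu is score-equivalent: Markov-equivalent
DAGs receive identical scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .dag import Dag
from .discretize import DiscreteTable

DEFAULT_ESS = 1.0


@dataclass(frozen=True)
class ScoredNetwork:
    """A DAG together with its log posterior score."""

    dag: Dag
    log_posterior: float


class BDeuScorer:
    """Cached family-score evaluator for one discrete data set.

    Family scores are memoized by (child, frozen parent set), so repeated
    queries during search cost one dictionary lookup.
    """

    def __init__(self, data: DiscreteTable, ess: float = DEFAULT_ESS) -> None:
        if ess <= 0:
            raise ValueError("ess must be positive")
        self.ess = float(ess)
        self.variables = list(data.variables)
        self._cols = {v: data.column(v) for v in self.variables}
        self._r = {v: int(data.cardinality[v]) for v in self.variables}
        self.n_rows = len(data.data)
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def family(self, child: str, parents: frozenset[str] | set[str]) -> float:
        key = (child, frozenset(parents))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        score = self._compute(child, sorted(key[1]))
        self._cache[key] = score
        return score

    def _compute(self, child: str, parents: list[str]) -> float:
        if child not in self._cols:
            raise KeyError(f"unknown variable {child!r}")
        for p in parents:
            if p not in self._cols:
                raise KeyError(f"unknown variable {p!r}")
        if child in parents:
            raise ValueError("child cannot be its own parent")
        r = self._r[child]
        if self.n_rows == 0:
            return 0.0

        q = 1
        j = np.zeros(self.n_rows, dtype=np.int64)
        for p in parents:
            j = j * self._r[p] + self._cols[p]
            q *= self._r[p]

        cell = j * r + self._cols[child]
        if q * r <= 4_000_000:
            counts = np.bincount(cell, minlength=q * r).reshape(q, r)
            nj = counts.sum(axis=1)
            occupied = nj > 0
            counts = counts[occupied]
            nj = nj[occupied]
        else:  # huge parent-configuration spaces: count occupied cells only
            cell_vals, cell_counts = np.unique(cell, return_counts=True)
            jj = cell_vals // r
            j_vals, inverse = np.unique(jj, return_inverse=True)
            counts_flat = cell_counts
            nj = np.zeros(len(j_vals), dtype=np.int64)
            np.add.at(nj, inverse, counts_flat)
            # cells with zero count contribute exactly 0 to the k-sum
            a_jk = self.ess / (q * r)
            a_j = self.ess / q
            score = float(
                np.sum(gammaln(a_j) - gammaln(a_j + nj))
                + np.sum(gammaln(a_jk + counts_flat) - gammaln(a_jk))
            )
            return score

        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        # zero-count cells contribute lnG(a)-lnG(a) = 0, safe to vectorize
        score = float(
            np.sum(gammaln(a_j) - gammaln(a_j + nj))
            + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
        )
        return score

    def score_dag(self, dag: Dag) -> float:
        return sum(self.family(v, dag.parents(v)) for v in dag.nodes)


def family_score(
    data: DiscreteTable, child: str, parents: set[str] | frozenset[str],
    ess: float = DEFAULT_ESS,
) -> float:
    """BDeu log marginal likelihood of one family (child given parents)."""
    return BDeuScorer(data, ess).family(child, frozenset(parents))


def score_dag(data: DiscreteTable, dag: Dag, ess: float = DEFAULT_ESS) -> ScoredNetwork:
    """Score a full DAG; the log posterior is the sum of its family scores."""
    missing = [n for n in dag.nodes if n not in data.variables]
    if missing:
        raise KeyError(f"DAG nodes absent from data: {missing}")
    dag.topological_order()  # raises CycleError on cyclic input
    scorer = BDeuScorer(data, ess)
    return ScoredNetwork(dag.copy(), scorer.score_dag(dag))
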