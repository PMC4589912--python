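"""Structure search: simulated annealing plus an exhaustive oracle.

``anneal_search`` is the production search: restarted simulated annealing
over DAG space with single-edge moves (add / delete / reverse), Metropolis
acceptance on the BDeu score difference, and geometric cooling.
``exhaustive_search`` enumerates every labeled DAG on small variable sets
(<= 5) and is used as the correctness oracle for the annealer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .dag import Dag
from .discretize import DiscreteTable
from .score import DEFAULT_ESS, BDeuScorer, ScoredNetwork

SCORE_TOL = 1e-9
_ENUM_LIMIT = 5


@dataclass
class SearchConfig:
    """Annealing-search configuration.

    Desk-scale defaults (20 restarts x 1e5 proposals) are sized for a
    single workstation CPU; the original analysis scale (100 restarts x
    5e7 proposals per compartment) is reachable by raising the two effort
    fields.  Cooling is geometric: the temperature is multiplied by
    ``cooling_factor`` every ``max(1, proposals_per_restart // 1000)``
    proposals, so a full anneal spans the run regardless of its length.

    The default initial temperature (10) is on the scale of typical
    single-edge score differences.  Much hotter starts let the random
    walk fill every node to the parent cap with junk edges, and BDeu at
    small ESS then traps the cooled search on plateaus where no single
    deletion improves the score.
    """

    ess: float = DEFAULT_ESS
    max_parents: int = 5
    n_restarts: int = 20
    proposals_per_restart: int = 100_000
    initial_temperature: float = 10.0
    cooling_factor: float = 0.95
    seed: int = 0
    top_k_retained: int = 32
    score_tolerance: float = SCORE_TOL

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise ValueError("ess must be positive")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if self.n_restarts < 1 or self.proposals_per_restart < 1:
            raise ValueError("restarts and proposals must be positive")
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.top_k_retained < 1:
            raise ValueError("top_k_retained must be >= 1")


# ---------------------------------------------------------------------------
# Exhaustive oracle


def enumerate_dags(nodes: tuple[str, ...]) -> Iterator[dict[str, frozenset[str]]]:
    """Yield every labeled DAG on ``nodes`` once, as parent maps.

    Enumerates (permutation, predecessor-subset) pairs and deduplicates by
    edge set; feasible up to 5 nodes (29 281 DAGs).
    """
    from itertools import combinations, permutations

    n = len(nodes)
    seen: set[frozenset[tuple[str, str]]] = set()
    for order in permutations(range(n)):
        choices: list[list[frozenset[str]]] = []
        for pos in range(n):
            preds = [nodes[order[i]] for i in range(pos)]
            subsets = [
                frozenset(c)
                for k in range(len(preds) + 1)
                for c in combinations(preds, k)
            ]
            choices.append(subsets)

        def rec(pos: int, parents: dict[str, frozenset[str]]):
            if pos == n:
                key = frozenset(
                    (p, c) for c, ps in parents.items() for p in ps
                )
                if key not in seen:
                    seen.add(key)
                    yield dict(parents)
                return
            node = nodes[order[pos]]
            for subset in choices[pos]:
                parents[node] = subset
                yield from rec(pos + 1, parents)
            del parents[node]

        yield from rec(0, {})


def exhaustive_search(
    data: DiscreteTable, ess: float = DEFAULT_ESS,
    score_tolerance: float = SCORE_TOL,
) -> list[ScoredNetwork]:
    """Enumerate and score every DAG; return all maximizers (ties kept).

    Limited to 5 variables; beyond that the labeled-DAG count explodes.
    """
    nodes = tuple(data.variables)
    if len(nodes) > _ENUM_LIMIT:
        raise ValueError(
            f"exhaustive search limited to {_ENUM_LIMIT} variables, got {len(nodes)}"
        )
    scorer = BDeuScorer(data, ess)
    best = -math.inf
    best_maps: list[dict[str, frozenset[str]]] = []
    for parents in enumerate_dags(nodes):
        score = sum(scorer.family(v, ps) for v, ps in parents.items())
        if score > best + score_tolerance:
            best = score
            best_maps = [parents]
        elif score >= best - score_tolerance:
            best_maps.append(parents)
    out = []
    for pm in best_maps:
        dag = Dag(nodes, [(p, c) for c, ps in pm.items() for p in ps])
        out.append(ScoredNetwork(dag, sum(
            scorer.family(v, pm[v]) for v in nodes)))
    return out


# ---------------------------------------------------------------------------
# Simulated annealing


def _has_path(children: dict[str, set[str]], src: str, dst: str,
              skip: tuple[str, str] | None = None) -> bool:
    """Directed reachability src -> dst, optionally ignoring one edge."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if skip is not None and u == skip[0] and v == skip[1]:
                continue
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def _anneal_one(scorer: BDeuScorer, nodes: tuple[str, ...],
                config: SearchConfig, rng: np.random.Generator
                ) -> list[tuple[float, frozenset[tuple[str, str]]]]:
    """One annealing restart from the empty DAG.

    Returns the restart's best score with every distinct co-best edge set
    found within ``score_tolerance`` of it (capped at top_k_retained).
    """
    n = len(nodes)
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    children: dict[str, set[str]] = {v: set() for v in nodes}
    fam = {v: scorer.family(v, frozenset()) for v in nodes}
    current = sum(fam.values())

    tol = config.score_tolerance
    best = current
    best_sets: dict[frozenset[tuple[str, str]], None] = {frozenset(): None}

    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    n_pairs = len(pairs)
    if n_pairs == 0:  # single variable: no legal moves exist
        return [(best, frozenset())]
    temp = config.initial_temperature
    cool_every = max(1, config.proposals_per_restart // 1000)
    family = scorer.family

    def snapshot() -> frozenset[tuple[str, str]]:
        return frozenset((p, c) for c, ps in parents.items() for p in ps)

    done = 0
    total = config.proposals_per_restart
    chunk_size = min(total, 8192)
    cool = config.cooling_factor
    while done < total:
        m = min(chunk_size, total - done)
        pair_idx = rng.integers(0, n_pairs, size=m)
        coins = rng.random(size=m)
        accepts = rng.random(size=m)
        for i in range(m):
            if (done + i + 1) % cool_every == 0:
                temp *= cool
            u, v = pairs[pair_idx[i]]
            delta = None
            move = None
            if v in children[u]:  # existing edge: delete or reverse
                if coins[i] < 0.5:
                    new_v = family(v, frozenset(parents[v] - {u}))
                    delta = new_v - fam[v]
                    move = ("del", u, v, new_v, None)
                else:
                    if len(parents[u]) < config.max_parents and not _has_path(
                        children, u, v, skip=(u, v)
                    ):
                        new_v = family(v, frozenset(parents[v] - {u}))
                        new_u = family(u, frozenset(parents[u] | {v}))
                        delta = (new_v - fam[v]) + (new_u - fam[u])
                        move = ("rev", u, v, new_v, new_u)
            else:  # add u -> v
                if len(parents[v]) < config.max_parents and not _has_path(
                    children, v, u
                ):
                    new_v = family(v, frozenset(parents[v] | {u}))
                    delta = new_v - fam[v]
                    move = ("add", u, v, new_v, None)

            if move is None:
                continue  # illegal proposal: rejected, consumes a step
            if delta < 0:
                ratio = delta / temp if temp > 1e-300 else -math.inf
                if ratio < -700 or accepts[i] >= math.exp(ratio):
                    continue

            kind, u, v, new_v, new_u = move
            if kind == "add":
                parents[v].add(u)
                children[u].add(v)
            elif kind == "del":
                parents[v].discard(u)
                children[u].discard(v)
            else:
                parents[v].discard(u)
                children[u].discard(v)
                parents[u].add(v)
                children[v].add(u)
                fam[u] = new_u
            fam[v] = new_v
            current += delta

            if current > best + tol:
                best = current
                best_sets = {snapshot(): None}
            elif current >= best - tol and len(best_sets) < config.top_k_retained:
                best_sets.setdefault(snapshot(), None)
        done += m
    return [(best, key) for key in best_sets]


def anneal_search(data: DiscreteTable, config: SearchConfig | None = None,
                  scorer: BDeuScorer | None = None) -> list[ScoredNetwork]:
    """Restarted simulated-annealing search over DAG space.

    Each restart begins at the empty DAG, proposes uniformly random
    single-edge moves (cycle-creating and parent-limit-violating proposals
    are rejected), accepts score-improving moves always and worsening
    moves with probability exp(delta/T), and cools geometrically.  The
    per-restart best networks (including score ties within tolerance) are
    pooled and returned sorted by descending score.  Fully reproducible
    from ``config.seed``.
    """
    if config is None:
        config = SearchConfig()
    if len(data.data) == 0:
        raise ValueError("data must be non-empty")
    if scorer is None:
        scorer = BDeuScorer(data, config.ess)
    nodes = tuple(data.variables)

    results: list[ScoredNetwork] = []
    seen: set[frozenset[tuple[str, str]]] = set()
    for restart in range(config.n_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), restart])
        )
        for score, edge_set in _anneal_one(scorer, nodes, config, rng):
            if edge_set in seen:
                continue
            seen.add(edge_set)
            results.append(ScoredNetwork(Dag(nodes, sorted(edge_set)), score))
    results.sort(key=lambda sn: -sn.log_posterior)
    return results
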