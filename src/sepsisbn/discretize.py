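"""Three-state discretization of continuous mediator columns.

The structure-learning stage operates on categorical data: every
continuous mediator is binned into 3 states, while the discrete condition
columns (CLP, LungInsult, InjuryInterval, type) pass through untouched
with their declared cardinalities.

The default policy is equal-frequency tertiles (cuts at the empirical 1/3
and 2/3 quantiles, snapped to midpoints between adjacent distinct order
statistics so the mapping is unambiguous); a manual policy loads expert
bin edges from a JSON file.  Intervals are closed on the right: a value
exactly at a cut point maps to the lower state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CONDITION_CARDINALITIES

EQUAL_FREQUENCY = "tertiles"
MANUAL = "manual"


@dataclass(frozen=True)
class ColumnScheme:
    """Bin edges for one continuous column.

    ``n_states = len(edges) + 1``; fewer than 3 states marks the column
    degenerate (too few distinct values to support tertiles).
    """

    edges: tuple[float, ...]
    policy: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_states(self) -> int:
        return len(self.edges) + 1


@dataclass
class DiscretizationScheme:
    """Per-variable bin edges plus the set of pass-through condition columns."""

    columns: dict[str, ColumnScheme]
    condition_vars: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition_vars": list(self.condition_vars),
            "columns": {
                name: {
                    "edges": list(cs.edges),
                    "policy": cs.policy,
                    "degenerate": cs.degenerate,
                }
                for name, cs in self.columns.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretizationScheme":
        payload = json.loads(Path(path).read_text())
        columns = {
            name: ColumnScheme(
                edges=tuple(spec["edges"]),
                policy=spec.get("policy", MANUAL),
                degenerate=bool(spec.get("degenerate", False)),
            )
            for name, spec in payload["columns"].items()
        }
        return cls(columns=columns, condition_vars=tuple(payload["condition_vars"]))


@dataclass
class DiscreteTable:
    """Integer-coded table plus per-column state counts r_i."""

    data: pd.DataFrame
    cardinality: dict[str, int]

    def __post_init__(self) -> None:
        for col in self.data.columns:
            r = self.cardinality.get(col)
            if r is None or r < 1:
                raise ValueError(f"missing/invalid cardinality for {col!r}")
            vals = self.data[col].to_numpy()
            if len(vals) and (vals.min() < 0 or vals.max() >= r):
                raise ValueError(f"column {col!r} has codes outside 0..{r - 1}")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=np.int64)


def _tertile_edges(values: np.ndarray) -> tuple[tuple[float, ...], bool]:
    """Equal-frequency cut points, snapped between adjacent distinct values."""
    distinct = np.unique(values)
    if distinct.size == 1:
        return (), True
    edges = []
    for q in (1 / 3, 2 / 3):
        qv = np.quantile(values, q)
        below = distinct[distinct <= qv]
        above = distinct[distinct > qv]
        if below.size == 0 or above.size == 0:
            continue
        edges.append(float((below[-1] + above[0]) / 2.0))
    edges = tuple(sorted(set(edges)))
    return edges, len(edges) < 2


def fit_bins(
    table: pd.DataFrame,
    policy: str = EQUAL_FREQUENCY,
    manual_edges: dict[str, tuple[float, float]] | None = None,
    condition_vars: tuple[str, ...] | None = None,
) -> DiscretizationScheme:
    """Fit a discretization scheme on a sample table.

    Columns listed in ``condition_vars`` (default: every column whose name
    has a declared condition cardinality) are passed through; all others
    are treated as continuous and binned into 3 states.
    """
    if condition_vars is None:
        condition_vars = tuple(
            c for c in table.columns if c in CONDITION_CARDINALITIES
        )
    continuous = [c for c in table.columns if c not in condition_vars]

    columns: dict[str, ColumnScheme] = {}
    if policy == EQUAL_FREQUENCY:
        for col in continuous:
            values = table[col].to_numpy(dtype=float)
            if np.isnan(values).any():
                raise ValueError(f"column {col!r} contains NaN")
            edges, degenerate = _tertile_edges(values)
            columns[col] = ColumnScheme(edges, EQUAL_FREQUENCY, degenerate)
    elif policy == MANUAL:
        if manual_edges is None:
            raise ValueError("manual policy requires explicit bin edges")
        for col in continuous:
            if col not in manual_edges:
                raise ValueError(f"manual edges missing for column {col!r}")
            edges = tuple(float(e) for e in manual_edges[col])
            columns[col] = ColumnScheme(edges, MANUAL, degenerate=len(edges) < 2)
    else:
        raise ValueError(f"unknown discretization policy {policy!r}")
    return DiscretizationScheme(columns=columns, condition_vars=condition_vars)


def apply_bins(table: pd.DataFrame, scheme: DiscretizationScheme) -> DiscreteTable:
    """Apply a fitted scheme: continuous columns -> state codes 0..2.

    Right-closed convention: values <= first cut map to state 0, values <=
    second cut to state 1, else state 2.  Condition columns are copied
    verbatim and keep their declared cardinalities.
    """
    out: dict[str, np.ndarray] = {}
    cards: dict[str, int] = {}
    for col in table.columns:
        if col in scheme.condition_vars:
            codes = table[col].to_numpy()
            if not np.issubdtype(codes.dtype, np.integer):
                as_int = codes.astype(np.int64)
                if not np.array_equal(as_int, codes):
                    raise ValueError(f"condition column {col!r} is not integer-coded")
                codes = as_int
            out[col] = codes.astype(np.int64)
            cards[col] = CONDITION_CARDINALITIES.get(
                col, int(codes.max()) + 1 if len(codes) else 1
            )
        else:
            if col not in scheme.columns:
                raise ValueError(f"column {col!r} missing from scheme")
            values = table[col].to_numpy(dtype=float)
            if np.isnan(values).any():
                raise ValueError(f"column {col!r} contains NaN")
            cs = scheme.columns[col]
            edges = np.asarray(cs.edges, dtype=float)
            out[col] = np.searchsorted(edges, values, side="left").astype(np.int64)
            cards[col] = cs.n_states
    return DiscreteTable(pd.DataFrame(out, columns=list(table.columns)), cards)


def discretize(
    table: pd.DataFrame,
    policy: str = EQUAL_FREQUENCY,
    manual_edges: dict[str, tuple[float, float]] | None = None,
    condition_vars: tuple[str, ...] | None = None,
) -> tuple[DiscreteTable, DiscretizationScheme]:
    """Fit and apply in one step (the common pipeline path)."""
    scheme = fit_bins(table, policy, manual_edges, condition_vars)
    return apply_bins(table, scheme), scheme
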