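"""Conventional group-wise statistics: mean ± SEM, t tests, ANOVA + Tukey.

These reproduce the standard analysis surface the network results are
contrasted with: per-group summaries and per-factor significance tests at
alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .design import CONDITION_VARS

ALPHA = 0.05


@dataclass
class GroupSummary:
    group: tuple[int, ...]
    variable: str
    n: int
    mean: float
    sem: float  # NaN when n == 1


@dataclass
class PairwiseFlag:
    level_a: int
    level_b: int
    mean_diff: float
    p_adj: float
    significant: bool


@dataclass
class ComparisonResult:
    variable: str
    factor: str
    test: str  # "t" or "anova+tukey"
    statistic: float
    p_value: float
    pairwise: list[PairwiseFlag] = field(default_factory=list)


def group_summary(table: pd.DataFrame, variable: str,
                  condition_vars: tuple[str, ...] = CONDITION_VARS
                  ) -> list[GroupSummary]:
    """Mean ± SEM of one mediator per design group present in the table."""
    if variable not in table.columns:
        raise KeyError(f"unknown variable {variable!r}")
    cols = [c for c in condition_vars if c in table.columns]
    out: list[GroupSummary] = []
    for key, sub in table.groupby(cols, sort=True):
        values = sub[variable].to_numpy(dtype=float)
        n = len(values)
        if n == 1:
            warnings.warn(
                f"group {key} has a single animal; SEM undefined", stacklevel=2
            )
            sem = float("nan")
        else:
            sem = float(np.std(values, ddof=1) / np.sqrt(n))
        key = key if isinstance(key, tuple) else (key,)
        out.append(GroupSummary(tuple(int(k) for k in key), variable, n,
                                float(np.mean(values)), sem))
    return out


def compare_groups(table: pd.DataFrame, variable: str, factor: str,
                   alpha: float = ALPHA, welch: bool = False) -> ComparisonResult:
    """Compare a mediator across the levels of one condition factor.

    Two levels: Student's t test (pooled variance; Welch behind a flag).
    More than two: one-way ANOVA with post hoc Tukey HSD pairwise flags.
    """
    if variable not in table.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if factor not in table.columns:
        raise KeyError(f"unknown factor {factor!r}")
    groups = {
        int(level): sub[variable].to_numpy(dtype=float)
        for level, sub in table.groupby(factor, sort=True)
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError(
            f"factor {factor!r} needs >= 2 levels with >= 2 observations each"
        )

    levels = sorted(groups)
    if len(levels) == 2:
        t, p = sps.ttest_ind(groups[levels[0]], groups[levels[1]],
                             equal_var=not welch)
        return ComparisonResult(variable, factor, "t", float(t), float(p))

    f, p = sps.f_oneway(*(groups[lv] for lv in levels))
    values = np.concatenate([groups[lv] for lv in levels])
    labels = np.concatenate([np.full(len(groups[lv]), lv) for lv in levels])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(tukey.groupsunique, 2))
    pairwise = [
        PairwiseFlag(int(a), int(b), float(diff), float(padj), bool(rej))
        for (a, b), diff, padj, rej in zip(
            pairs, tukey.meandiffs, tukey.pvalues, tukey.reject
        )
    ]
    return ComparisonResult(variable, factor, "anova+tukey", float(f), float(p),
                            pairwise)


def summary_frame(summaries: list[GroupSummary],
                  condition_vars: tuple[str, ...] = CONDITION_VARS) -> pd.DataFrame:
    """Tabulate group summaries (one row per group) for TSV export."""
    rows = []
    for s in summaries:
        row = dict(zip(condition_vars, s.group))
        row.update(variable=s.variable, n=s.n, mean=s.mean, sem=s.sem)
        rows.append(row)
    return pd.DataFrame(rows)
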