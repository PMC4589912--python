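"""Synthetic cohort generator.

No measurement data are deposited with the study this package models, so
every downstream stage (discretization, scoring, annealing search,
consensus, motifs, baseline statistics) is exercised against cohorts drawn
from a configurable ground-truth causal model.  The generator emulates the
study design (12 groups, three compartments, ~10 animals/group) and the
qualitative dependency structure reported for the real data, not the
biology itself: mediator concentrations are conditionally log-normal given
their parents, which captures the positivity and right skew of cytokine
panels but none of the temporal dynamics or mechanistic couplings.

Ground truth presets
--------------------
``paper-like``
    BAL neutrophils (NE) have the condition parents {CLP, LungInsult}
    (the collider motif), eosinophils (EO) are a child of NE (completing
    the "Y"), BAL albumin is downstream of NE, BAL CXC/CC chemokines (KC,
    MIP-2a, LIX, MCP-1) depend on LungInsult only; peritoneal and blood
    IL-6/TNF-a/IL-1b depend on {CLP, InjuryInterval}; peritoneal NE
    depends on CLP alone.  Blood NE is calibrated to the reported group
    means 1.9 (at CLP, 0 h) and 0.8 (12 h after CLP) x10^3 neutrophils/ul.
``strong``
    Same structure as ``paper-like`` with effect gaps widened (x1.6 in log
    space) and noise reduced; used for small structure-learning checks.
``null``
    Same marginal baselines, no dependencies at all.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    BAL,
    BLOOD,
    CLP,
    COMPARTMENTS,
    CONDITION_VARS,
    DEFAULT_PANEL,
    INJURY_INTERVAL,
    LUNG_INSULT,
    PERITONEUM,
    GroupSpec,
    MediatorPanel,
    enumerate_design,
)

GENERATOR_VERSION = "1"

#: Blood neutrophil calibration anchors, x10^3 neutrophils/ul: the reported
#: group means at the time of CLP (0 h) and 12 h after CLP.
BLOOD_NE_MEAN_0H = 1.9
BLOOD_NE_MEAN_12H = 0.8


@dataclass
class NodeModel:
    """Conditional log-normal model for one mediator.

    The mediator X is drawn as ``X = exp(N(mu, sigma^2))`` with

        mu = ln(m) - sigma^2/2 + sum_p coef_p * (ln(x_p) - ln(center_p))

    where ``m`` is the target conditional mean given the discrete condition
    parents (looked up in ``cond_means``, falling back to ``mean``) and the
    sum runs over continuous mediator parents.  With no mediator parents
    the conditional expectation of X is exactly ``m``, which is what the
    calibration anchors rely on.

    Parameters
    ----------
    mean : baseline mean on the natural scale (pg/ml for cytokines,
        x10^3 cells/ul for cell counts, ug/ml for albumin); also used as
        the centering constant when this node acts as a parent.
    sigma : log-scale standard deviation (dimensionless).
    cond_parents : discrete condition-variable parents, in lookup order.
    cond_means : mapping from tuples of parent state codes to conditional
        means; keys missing from the table fall back to ``mean``.
    med_parents : mapping mediator-parent name -> log-log coefficient.
    """

    mean: float
    sigma: float
    cond_parents: tuple[str, ...] = ()
    cond_means: dict[tuple[int, ...], float] = field(default_factory=dict)
    med_parents: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for m in self.cond_means.values():
            if m <= 0:
                raise ValueError("all conditional means must be positive")

    def parents(self) -> tuple[str, ...]:
        return self.cond_parents + tuple(self.med_parents)

    def conditional_mean(self, cond_codes: tuple[int, ...]) -> float:
        return self.cond_means.get(cond_codes, self.mean)


@dataclass
class CompartmentTruth:
    """Ground-truth model for one compartment: a DAG via per-node models."""

    compartment: str
    nodes: dict[str, NodeModel]

    def __post_init__(self) -> None:
        self.topo_order()  # raises on cycles / missing parents

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for child, model in self.nodes.items():
            for parent in model.parents():
                out.append((parent, child))
        return out

    def topo_order(self) -> list[str]:
        """Mediators in ancestral sampling order (condition vars excluded)."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited, 1 in stack, 2 done

        def visit(name: str) -> None:
            if state.get(name) == 2:
                return
            if state.get(name) == 1:
                raise ValueError(f"ground-truth graph has a cycle through {name!r}")
            state[name] = 1
            for parent in self.nodes[name].med_parents:
                if parent not in self.nodes:
                    raise ValueError(f"{name!r} has unknown parent {parent!r}")
                visit(parent)
            state[name] = 2
            order.append(name)

        for name in self.nodes:
            visit(name)
        return order


@dataclass
class CausalTruth:
    """Full ground truth: one :class:`CompartmentTruth` per compartment."""

    preset: str
    compartments: dict[str, CompartmentTruth]
    panel: MediatorPanel = field(default_factory=MediatorPanel)

    def edge_lists(self) -> dict[str, list[tuple[str, str]]]:
        return {c: t.edges() for c, t in self.compartments.items()}


# ---------------------------------------------------------------------------
# Presets

# Baseline means (natural scale) for mediators with no condition parents.
# Cytokines/chemokines in pg/ml, cells in x10^3 cells/ul, albumin in ug/ml.
_BASELINES: dict[str, tuple[float, float]] = {
    # name: (mean, sigma)
    "TNFa": (40.0, 0.7), "IL6": (60.0, 0.7), "IL1b": (35.0, 0.7),
    "IL12": (80.0, 0.7), "IFNg": (25.0, 0.7), "IL13": (15.0, 0.7),
    "IL4": (12.0, 0.7), "IL5": (18.0, 0.7), "IL18": (120.0, 0.7),
    "IL2": (10.0, 0.7),
    "IL10": (30.0, 0.7), "TNFsr1": (300.0, 0.6), "TNFsr2": (500.0, 0.6),
    "IL1ra": (150.0, 0.7),
    "MIP2a": (90.0, 0.7), "KC": (120.0, 0.7), "LIX": (60.0, 0.7),
    "MCP1": (70.0, 0.7), "MIP1a": (45.0, 0.7), "RANTES": (35.0, 0.7),
    "Eotaxin": (50.0, 0.7),
    "WBC": (6.0, 0.5), "NE": (1.5, 0.5), "MO": (0.8, 0.5),
    "LY": (3.5, 0.5), "EO": (0.15, 0.6),
    "Albumin": (60.0, 0.6),
}

# BAL chemokines driven by LungInsult only: per-chemokine scale applied to
# the severity profile saline < acid < particles.
_CHEMOKINE_PROFILE = {1: 150.0, 2: 900.0, 3: 2600.0}
_BAL_CHEMOKINE_SCALE = {"KC": 1.0, "MIP2a": 0.8, "LIX": 0.5, "MCP1": 0.6}

# Pro-inflammatory cytokines in peritoneum/blood driven by {CLP, interval}:
# low without CLP, peak at 12 h, partial resolution by 48 h.
_PROINF_PROFILE = {
    PERITONEUM: {
        "IL6": {0: 40.0, 1: 400.0, 2: 4000.0, 3: 600.0},
        "TNFa": {0: 25.0, 1: 200.0, 2: 1500.0, 3: 250.0},
        "IL1b": {0: 30.0, 1: 250.0, 2: 1800.0, 3: 300.0},
    },
    BLOOD: {
        "IL6": {0: 30.0, 1: 250.0, 2: 2000.0, 3: 350.0},
        "TNFa": {0: 20.0, 1: 120.0, 2: 800.0, 3: 150.0},
        "IL1b": {0: 25.0, 1: 150.0, 2: 1000.0, 3: 200.0},
    },
}

# BAL neutrophils: severity-graded recruitment, suppressed by concurrent CLP.
_BAL_NE_NO_CLP = {1: 40.0, 2: 180.0, 3: 550.0}
_BAL_NE_CLP_FACTOR = 0.3

# Blood neutrophils by (CLP, interval); anchored to the reported means at
# 0 h and 12 h, with a partial rebound at 48 h.
_BLOOD_NE_MEANS = {
    (0, 0): BLOOD_NE_MEAN_0H,
    (1, 1): BLOOD_NE_MEAN_0H,
    (1, 2): BLOOD_NE_MEAN_12H,
    (1, 3): 1.3,
}

_PERITONEAL_NE_MEANS = {(0,): 0.4, (1,): 3.5}


def _interval_table(profile: dict[int, float]) -> dict[tuple[int, int], float]:
    """Expand an interval profile to a (CLP, InjuryInterval) mean table."""
    table = {(0, 0): profile[0]}
    for interval in (1, 2, 3):
        table[(1, interval)] = profile[interval]
    return table


def default_truth(effect_profile: str = "paper-like") -> CausalTruth:
    """Build a shipped ground-truth preset ("paper-like", "strong", "null")."""
    if effect_profile not in ("paper-like", "strong", "null"):
        raise ValueError(f"unknown effect profile {effect_profile!r}")

    panel = DEFAULT_PANEL
    compartments: dict[str, CompartmentTruth] = {}
    for comp in COMPARTMENTS:
        nodes: dict[str, NodeModel] = {}
        for name in panel.variables(comp):
            mean, sigma = _BASELINES[name]
            nodes[name] = NodeModel(mean=mean, sigma=sigma)
        compartments[comp] = CompartmentTruth(comp, nodes)

    if effect_profile == "null":
        return CausalTruth("null", compartments, panel)

    # BAL: the collider, the Y tail, albumin leak, insult-driven chemokines.
    bal = compartments[BAL].nodes
    bal_ne_means = {}
    for insult, m in _BAL_NE_NO_CLP.items():
        bal_ne_means[(0, insult)] = m
        bal_ne_means[(1, insult)] = m * _BAL_NE_CLP_FACTOR
    bal["NE"] = NodeModel(
        mean=120.0, sigma=0.5, cond_parents=(CLP, LUNG_INSULT),
        cond_means=bal_ne_means,
    )
    bal["EO"] = NodeModel(
        mean=0.6, sigma=0.5, med_parents={"NE": 0.8},
    )
    bal["Albumin"] = NodeModel(
        mean=60.0, sigma=0.5, med_parents={"NE": 0.6},
    )
    for chem, scale in _BAL_CHEMOKINE_SCALE.items():
        bal[chem] = NodeModel(
            mean=100.0 * scale, sigma=0.6, cond_parents=(LUNG_INSULT,),
            cond_means={(i,): m * scale for i, m in _CHEMOKINE_PROFILE.items()},
        )

    # Peritoneum / blood: CLP + interval drive the pro-inflammatory triad.
    for comp in (PERITONEUM, BLOOD):
        nodes = compartments[comp].nodes
        for cyt, profile in _PROINF_PROFILE[comp].items():
            nodes[cyt] = NodeModel(
                mean=profile[0], sigma=0.6,
                cond_parents=(CLP, INJURY_INTERVAL),
                cond_means=_interval_table(profile),
            )
    compartments[PERITONEUM].nodes["NE"] = NodeModel(
        mean=0.4, sigma=0.5, cond_parents=(CLP,),
        cond_means=dict(_PERITONEAL_NE_MEANS),
    )
    compartments[BLOOD].nodes["NE"] = NodeModel(
        mean=BLOOD_NE_MEAN_0H, sigma=0.35,
        cond_parents=(CLP, INJURY_INTERVAL),
        cond_means=dict(_BLOOD_NE_MEANS),
    )

    # Re-validate after edits (acyclicity, parent resolution).
    compartments = {
        c: CompartmentTruth(c, t.nodes) for c, t in compartments.items()
    }
    truth = CausalTruth(effect_profile, compartments, panel)

    if effect_profile == "strong":
        _amplify(truth, log_gap_factor=1.6, sigma_factor=0.7)
    return truth


def _amplify(truth: CausalTruth, log_gap_factor: float, sigma_factor: float) -> None:
    """Widen conditional-mean gaps in log space and shrink noise, in place."""
    for comp_truth in truth.compartments.values():
        for model in comp_truth.nodes.values():
            if model.cond_means:
                logs = [math.log(m) for m in model.cond_means.values()]
                center = sum(logs) / len(logs)
                model.cond_means = {
                    k: math.exp(center + log_gap_factor * (math.log(v) - center))
                    for k, v in model.cond_means.items()
                }
            model.med_parents = {
                p: c * log_gap_factor for p, c in model.med_parents.items()
            }
            model.sigma *= sigma_factor


# ---------------------------------------------------------------------------
# Cohort sampling


@dataclass
class SampleTable:
    """Per-compartment animal-by-variable table with provenance."""

    compartment: str
    data: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "observed"})

    @property
    def mediators(self) -> list[str]:
        return [c for c in self.data.columns if c not in CONDITION_VARS]


def generate_cohort(
    truth: CausalTruth,
    design: list[GroupSpec] | None = None,
    n_per_group: int | None = None,
    seed: int = 0,
) -> dict[str, SampleTable]:
    """Draw a synthetic cohort by ancestral sampling from the ground truth.

    One table per compartment; rows are animals, ordered by design group.
    ``n_per_group`` overrides every group's size when given.  Sampling is
    fully reproducible: identical (truth, design, n_per_group, seed) give
    byte-identical tables.
    """
    if design is None:
        design = enumerate_design()
    if not design:
        raise ValueError("design must contain at least one group")
    if n_per_group is not None:
        if n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        design = [GroupSpec(g.condition, n_per_group) for g in design]

    cond_cols: dict[str, np.ndarray] = {}
    for j, var in enumerate(CONDITION_VARS):
        cond_cols[var] = np.concatenate(
            [np.full(g.n_animals, g.condition.as_tuple()[j], dtype=np.int64)
             for g in design]
        )
    n_rows = len(cond_cols[CLP])

    tables: dict[str, SampleTable] = {}
    for ci, comp in enumerate(COMPARTMENTS):
        comp_truth = truth.compartments[comp]
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), ci]))
        values: dict[str, np.ndarray] = {}
        for name in comp_truth.topo_order():
            model = comp_truth.nodes[name]
            mu = np.full(n_rows, math.log(model.mean) - 0.5 * model.sigma**2)
            if model.cond_parents:
                keys = list(zip(*(cond_cols[p] for p in model.cond_parents)))
                means = np.array([model.conditional_mean(k) for k in keys])
                mu = np.log(means) - 0.5 * model.sigma**2
            for parent, coef in model.med_parents.items():
                center = math.log(comp_truth.nodes[parent].mean)
                mu = mu + coef * (np.log(values[parent]) - center)
            values[name] = np.exp(rng.normal(mu, model.sigma))

        df = pd.DataFrame({**cond_cols}, copy=True)
        for name in comp_truth.nodes:  # panel order, not topo order
            df[name] = values[name]
        tables[comp] = SampleTable(
            comp,
            df,
            provenance={
                "source": "synthetic",
                "preset": truth.preset,
                "seed": int(seed),
                "generator_version": GENERATOR_VERSION,
            },
        )
    return tables


def write_cohort(tables: dict[str, SampleTable], outdir: str | Path,
                 truth: CausalTruth | None = None) -> list[Path]:
    """Write one CSV per compartment plus a JSON provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sidecar: dict = {"compartments": {}}
    for comp, table in tables.items():
        path = outdir / f"{comp}.csv"
        table.data.to_csv(path, index=False)
        written.append(path)
        sidecar["compartments"][comp] = {
            "path": path.name,
            "n_rows": int(len(table.data)),
            **table.provenance,
        }
    if truth is not None:
        sidecar["truth_edges"] = {
            comp: [list(e) for e in edges]
            for comp, edges in truth.edge_lists().items()
        }
    sidecar_path = outdir / "cohort.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written.append(sidecar_path)
    return written


def read_cohort(paths: dict[str, str | Path]) -> dict[str, SampleTable]:
    """Load per-compartment CSV tables (compartment name -> path)."""
    tables = {}
    for comp, path in paths.items():
        if comp not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {comp!r}")
        df = pd.read_csv(path)
        missing = [v for v in CONDITION_VARS if v not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing condition columns {missing}")
        tables[comp] = SampleTable(comp, df, provenance={"source": str(path)})
    return tables
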