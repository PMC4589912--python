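"""End-to-end pipeline: simulate/ingest -> discretize -> search -> consensus.

Mirrors the original analysis layout: one structure-learning run per
compartment (peritoneum, blood, BAL) plus a combined run in which the
three tables are stacked and a 3-state ``type`` variable records the fluid
source.  Albumin, measured in BAL only, is dropped from the combined run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .consensus import CONSENSUS_TOL, ConsensusNetwork, MotifReport
from .design import (
    BAL,
    COMPARTMENT_CODES,
    COMPARTMENTS,
    CONDITION_VARS,
    TYPE,
    enumerate_design,
)
from .generate import SampleTable, default_truth, generate_cohort, read_cohort
from .model import BNResults, CompartmentBNModel


@dataclass
class PipelineConfig:
    """One config object drives simulate/ingest plus all analysis stages."""

    mode: str = "simulate"  # "simulate" | "csv"
    csv_paths: dict[str, str] = field(default_factory=dict)
    preset: str = "paper-like"
    n_per_group: int = 10
    seed: int = 0
    policy: str = "tertiles"
    manual_edges_path: str | None = None
    ess: float = 1.0
    max_parents: int = 5
    n_restarts: int = 20
    proposals_per_restart: int = 100_000
    consensus_tolerance: float = CONSENSUS_TOL
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "csv"):
            raise ValueError("mode must be 'simulate' or 'csv'")
        if self.mode == "csv" and not self.csv_paths:
            raise ValueError("csv mode requires csv_paths")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class CompartmentResult:
    compartment: str
    results: BNResults
    log: dict

    @property
    def consensus(self) -> ConsensusNetwork:
        return self.results.consensus

    def motifs(self) -> MotifReport:
        return self.results.motifs()


def load_tables(config: PipelineConfig) -> dict[str, SampleTable]:
    if config.mode == "simulate":
        truth = default_truth(config.preset)
        return generate_cohort(
            truth, enumerate_design(), config.n_per_group, config.seed
        )
    return read_cohort(config.csv_paths)


def _manual_edges(config: PipelineConfig) -> dict | None:
    if config.manual_edges_path is None:
        return None
    payload = json.loads(Path(config.manual_edges_path).read_text())
    return {k: tuple(v) for k, v in payload.items()}


def _run_table(
    config: PipelineConfig, table: pd.DataFrame, tag: str,
    compartment: str | None = None,
) -> CompartmentResult:
    t0 = time.perf_counter()
    model = CompartmentBNModel(
        table,
        policy=config.policy,
        manual_edges=_manual_edges(config),
        ess=config.ess,
        max_parents=config.max_parents,
    )
    model.compartment = compartment or tag
    results = model.fit(
        n_restarts=config.n_restarts,
        proposals_per_restart=config.proposals_per_restart,
        seed=config.seed,
        consensus_tolerance=config.consensus_tolerance,
    )
    log = {
        "stage": tag,
        "seed": config.seed,
        "n_rows": int(len(table)),
        "n_variables": int(len(model.discrete.variables)),
        "n_restarts": config.n_restarts,
        "proposals_per_restart": config.proposals_per_restart,
        "proposals_total": config.n_restarts * config.proposals_per_restart,
        "best_score": results.top_score,
        "n_top_networks": results.n_top_networks,
        "wall_seconds": round(time.perf_counter() - t0, 3),
    }
    out = CompartmentResult(tag, results, log)
    if config.outdir:
        _persist(config, out)
    return out


def _persist(config: PipelineConfig, result: CompartmentResult) -> None:
    outdir = Path(config.outdir) / result.compartment
    outdir.mkdir(parents=True, exist_ok=True)
    c = result.consensus
    c.write_edge_list(outdir / "consensus.edges.tsv")
    c.write_graphml(outdir / "consensus.graphml")
    (outdir / "consensus.dot").write_text(c.to_dot())
    result.motifs().to_json(outdir / "motifs.json")
    result.results.model.scheme.to_json(outdir / "bins.json")
    with open(outdir / "networks.scores.tsv", "w") as fh:
        fh.write("rank\tlog_posterior\tn_edges\n")
        for i, sn in enumerate(result.results.networks):
            fh.write(f"{i}\t{sn.log_posterior:.9f}\t{sn.dag.n_edges()}\n")
    for i, sn in enumerate(result.results.networks[: c.n_networks]):
        sn.dag.write_edge_list(outdir / f"top_{i:03d}.edges.tsv")
    with open(Path(config.outdir) / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(result.log, sort_keys=True) + "\n")


def run_compartment_analysis(
    config: PipelineConfig, compartment: str,
    tables: dict[str, SampleTable] | None = None,
) -> CompartmentResult:
    """Discretize, search, and build the consensus for one compartment."""
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    if tables is None:
        tables = load_tables(config)
    return _run_table(
        config, tables[compartment].data, compartment, compartment
    )


def stack_combined(tables: dict[str, SampleTable]) -> pd.DataFrame:
    """Stack the three compartment tables with the 3-state ``type`` column.

    Only mediators common to all compartments are kept (albumin, measured
    in BAL only, is dropped); condition columns are carried through.
    """
    missing = [c for c in COMPARTMENTS if c not in tables]
    if missing:
        raise ValueError(f"combined analysis needs all compartments; missing {missing}")
    mediator_sets = [
        {c for c in t.data.columns if c not in CONDITION_VARS}
        for t in tables.values()
    ]
    common = set.intersection(*mediator_sets)
    dropped = set.union(*mediator_sets) - common
    if dropped - {"Albumin"}:
        raise ValueError(
            f"compartment panels differ beyond the albumin exception: {dropped}"
        )
    # preserve BAL column order for the shared mediators
    ordered = [
        c for c in tables[BAL].data.columns
        if c in common and c not in CONDITION_VARS
    ]
    frames = []
    for comp in COMPARTMENTS:
        df = tables[comp].data[list(CONDITION_VARS) + ordered].copy()
        df.insert(len(CONDITION_VARS), TYPE, COMPARTMENT_CODES[comp])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_combined_analysis(
    config: PipelineConfig, tables: dict[str, SampleTable] | None = None
) -> CompartmentResult:
    """The fourth run: all compartments stacked with the ``type`` variable."""
    if tables is None:
        tables = load_tables(config)
    combined = stack_combined(tables)
    return _run_table(config, combined, "combined")


def run_all(config: PipelineConfig) -> dict[str, CompartmentResult]:
    """Per-compartment runs plus the combined run, as in the original design."""
    tables = load_tables(config)
    out = {
        comp: run_compartment_analysis(config, comp, tables)
        for comp in COMPARTMENTS
    }
    out["combined"] = run_combined_analysis(config, tables)
    return out
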