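"""End-to-end stepwise analysis: the chain the command-line tool drives.

A run takes a preprocessed table with assigned roles and executes, in
order: Monte-Carlo-validated compression of each multivariate covariate
block to a target score, stepwise covariate projection (univariate
covariates first by default, then block scores), a validated net PLS +
target-projection model at every adjustment stage, the per-variable
variance partition, block variance tables, and selectivity-fraction
importance profiles with Monte Carlo limits.

All randomness flows from one top-level seed, split deterministically per
stage with numpy's SeedSequence, so any stage can be re-run in isolation
with identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adjustment import (
    AdjustmentState,
    CompressionResult,
    NetModel,
    adjust_multivariate,
    adjust_univariate,
    compress_multivariate_covariate,
    net_model,
)
from .datatable import DataTable, preprocess, read_table
from .importance import ImportanceProfile, mc_importance_limits
from .partition import VariancePartition, block_variance_table, build_partition
from .validation import ValidationConfig

__all__ = ["RunConfig", "StageResult", "StudyResult", "stepwise_analysis", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative description of one analysis run (YAML/JSON round-trip)."""

    input_path: str = ""
    input_format: str | None = None
    outcome: str = "outcome"
    covariates: list[str] = field(default_factory=list)  # univariate, in order
    covariate_blocks: dict[str, list[str]] = field(default_factory=dict)
    explanatory: list[str] = field(default_factory=list)
    log_columns: list[str] = field(default_factory=list)
    standardize: bool = True
    n_rep: int = 1000
    A_max: int = 7
    threshold: float = 0.5
    split_fraction: float = 0.5
    cost: str = "RMSEP"
    seed: int = 0
    output_dir: str = "netpls_out"

    def validation_config(self, seed: int) -> ValidationConfig:
        return ValidationConfig(
            n_rep=self.n_rep,
            A_max=self.A_max,
            threshold=self.threshold,
            split_fraction=self.split_fraction,
            cost=self.cost,
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass
class StageResult:
    """One adjustment stage: state after its projections plus the net model."""

    label: str
    state: AdjustmentState
    net: NetModel
    partition: VariancePartition
    importance: ImportanceProfile | None


@dataclass
class StudyResult:
    """Everything a stepwise run produces."""

    stages: list[StageResult]
    compressions: dict[str, CompressionResult]
    blocks: dict[str, list[str]]
    config: RunConfig | None = None

    def block_table(self) -> pd.DataFrame:
        return block_variance_table(
            [(s.label, s.partition) for s in self.stages], self.blocks
        )

    @property
    def final(self) -> StageResult:
        return self.stages[-1]


def stepwise_analysis(
    table: DataTable,
    outcome: str,
    covariates: list[str],
    covariate_blocks: dict[str, list[str]],
    explanatory: list[str],
    config: RunConfig | None = None,
    with_importance: bool = True,
) -> StudyResult:
    """Run the full stepwise adjustment and modelling chain.

    Block scores are fit on the unadjusted data (outcome vs block), then
    univariate covariates are projected in the given order followed by the
    block scores.  A net model, variance partition, and (optionally) an
    importance profile are produced for every stage.
    """
    config = config or RunConfig()
    n_stages = 1 + len(covariates) + len(covariate_blocks)
    seeds = stage_seeds(config.seed, 2 * n_stages + len(covariate_blocks))
    seed_iter = iter(seeds)

    # 1. compress each covariate block on unadjusted data
    compressions: dict[str, CompressionResult] = {}
    y_raw = table.column(outcome)
    for name, cols in covariate_blocks.items():
        Z = np.column_stack([table.column(c) for c in cols])
        compressions[name] = compress_multivariate_covariate(
            Z, y_raw, config.validation_config(next(seed_iter))
        )

    block_cols = [c for cols in covariate_blocks.values() for c in cols]
    state = AdjustmentState.from_table(
        table,
        outcome,
        covariates=list(covariates) + block_cols,
        explanatory=list(explanatory),
    )

    def make_stage(label: str, st: AdjustmentState) -> StageResult:
        vc = config.validation_config(next(seed_iter))
        net = net_model(st, vc)
        part = build_partition(st, net)
        imp = None
        if with_importance and not net.is_null:
            imp = mc_importance_limits(
                st.net_X,
                st.net_y,
                net.pls.n_components,
                config.validation_config(next(seed_iter)),
                names=st.explanatory_names,
            )
        else:
            next(seed_iter)  # keep the seed stream aligned
        return StageResult(label=label, state=st, net=net, partition=part, importance=imp)

    stages = [make_stage("unadjusted", state)]
    running_label: list[str] = []
    for cov in covariates:
        state = adjust_univariate(state, cov)
        running_label.append(cov)
        stages.append(make_stage(" + ".join(running_label), state))
    for name in covariate_blocks:
        state = adjust_multivariate(state, compressions[name].score, label=name)
        running_label.append(name)
        stages.append(make_stage(" + ".join(running_label), state))

    blocks = {"outcome": [outcome]}
    blocks.update(covariate_blocks)
    # default explanatory grouping: one block for all explanatory variables
    blocks["explanatory"] = list(explanatory)
    return StudyResult(
        stages=stages, compressions=compressions, blocks=blocks, config=config
    )


def run_pipeline(config: RunConfig, table: DataTable | None = None) -> StudyResult:
    """Execute a RunConfig end to end and write artifacts to its output dir."""
    if table is None:
        table = read_table(config.input_path, format=config.input_format)
    report = table.validate()
    if report.missing:
        raise ValueError(f"validation failed, missing values in: {report.missing}")
    processed = preprocess(
        table, log_columns=config.log_columns, standardize=config.standardize
    )
    result = stepwise_analysis(
        processed,
        outcome=config.outcome,
        covariates=config.covariates,
        covariate_blocks=config.covariate_blocks,
        explanatory=config.explanatory,
        config=config,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.block_table().to_csv(out / "block_variance_table.csv")
    for stage in result.stages:
        tag = stage.label.replace(" ", "_").replace("+", "and")
        stage.partition.fractions.to_csv(out / f"partition_{tag}.csv")
        if stage.importance is not None:
            stage.importance.to_csv(out / f"importance_{tag}.csv")
        if not stage.net.is_null:
            (out / f"net_model_{tag}.json").write_text(
                json.dumps(
                    {
                        "selected_A": stage.net.pls.n_components,
                        "explained_y_fraction_of_original": stage.net.explained_y_fraction_of_original(),
                        "tp": stage.net.tp.to_dict(),
                    }
                )
            )
    summary = {
        "seed": config.seed,
        "stages": [s.label for s in result.stages],
        "compressions": {
            name: {
                "selected_A": c.selected_A,
                "explained_y_fraction": c.explained_y_fraction,
                "explained_block_fraction": c.explained_block_fraction,
            }
            for name, c in result.compressions.items()
        },
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return result
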