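"""Variance partitions: per-variable decompositions and block tables.

After stepwise covariate projection and the net target-projection model,
every variable's original sum of squares splits into orthogonal parts: one
per covariate projection, one net predictive part, and a residual.  The
per-variable fractions feed variance plots; aggregating them over named
variable blocks (outcome, adiposity, physical-activity spectrum, mediator
block) reproduces the remaining/explained-variance tables of a stepwise
adjustment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjustment import AdjustmentState, NetModel

__all__ = ["VariancePartition", "build_partition", "block_variance_table"]


@dataclass
class VariancePartition:
    """Per-variable fractions of original variance, one column per part.

    ``fractions`` has one row per variable and one column per covariate
    projection, plus ``net`` and ``residual``; every row sums to 1.
    ``original_ss`` keeps the denominators for SS-weighted aggregation.
    """

    fractions: pd.DataFrame
    original_ss: pd.Series
    roles: dict[str, str]

    @property
    def parts(self) -> list[str]:
        return list(self.fractions.columns)

    def row_sums(self) -> pd.Series:
        return self.fractions.sum(axis=1)

    def display(self) -> pd.DataFrame:
        """Fractions clipped to [0, 1] for plotting/tabulation."""
        return self.fractions.clip(lower=0.0)

    def block_fraction(self, names: list[str], part: str) -> float:
        """SS-weighted mean fraction of ``part`` over a variable block."""
        ss = self.original_ss.loc[names]
        return float((self.fractions.loc[names, part] * ss).sum() / ss.sum())

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.fractions.reset_index(names="variable").melt(
            id_vars="variable", var_name="part", value_name="fraction"
        )
        return tidy


def build_partition(state: AdjustmentState, net: NetModel | None) -> VariancePartition:
    """Assemble the per-variable partition from the ledger plus the net model.

    The net part of an explanatory variable is the SS captured by the net
    target component; for the outcome it is the SS of the net fitted
    outcome.  Covariate columns (fully consumed by their own projection)
    have a zero net part.  The residual closes each row to 1.
    """
    names = state.column_names
    labels = [label for label, _ in state.projection_sequence]
    data: dict[str, np.ndarray] = {}
    denom = np.where(state.original_ss > 0, state.original_ss, 1.0)
    for label in labels:
        data[label] = state.removed_ss[label] / denom

    net_part = np.zeros(len(names))
    if net is not None and not net.is_null:
        per_var = net.tp.explained_X_per_variable()
        expl = state.explanatory_names
        if len(per_var) != len(expl):
            raise ValueError("net model dimensions do not match the adjustment state")
        for name, captured in zip(expl, per_var):
            j = state.index_of(name)
            net_part[j] = captured / denom[j]
        yhat = net.tp.fitted_y()
        j = state.index_of(state.outcome_name)
        net_part[j] = float(yhat @ yhat) / denom[j]
    data["net"] = net_part

    frac = pd.DataFrame(data, index=names)
    frac["residual"] = 1.0 - frac.sum(axis=1)
    # columns that are exactly zero from the start (projected covariates
    # re-partitioned later) keep residual 0, not 1
    zero = state.original_ss == 0
    if np.any(zero):
        frac.loc[np.asarray(names)[zero], "residual"] = 0.0
    return VariancePartition(
        fractions=frac,
        original_ss=pd.Series(state.original_ss, index=names),
        roles=dict(state.roles),
    )


def block_variance_table(
    stages: list[tuple[str, VariancePartition]],
    blocks: dict[str, list[str]],
) -> pd.DataFrame:
    """Remaining and model-explained variance per block across stages.

    For every adjustment stage and block: ``remaining`` is 100 x the
    residual-plus-net fraction (variance left after the covariate
    projections of that stage) and ``explained`` is 100 x the net target
    component's share — both relative to the original, unadjusted variance.
    """
    for name, members in blocks.items():
        for _, part in stages:
            missing = [m for m in members if m not in part.fractions.index]
            if missing:
                raise ValueError(
                    f"block {name!r}: columns {missing} absent from a stage partition"
                )
    rows = []
    for stage_label, part in stages:
        row: dict[str, float] = {"stage": stage_label}
        for block_name, members in blocks.items():
            remaining = part.block_fraction(members, "net") + part.block_fraction(
                members, "residual"
            )
            row[f"remaining_{block_name}"] = 100.0 * remaining
            row[f"explained_{block_name}"] = 100.0 * part.block_fraction(members, "net")
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")
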