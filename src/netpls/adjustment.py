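"""Stepwise covariate adjustment of the augmented matrix [y | Z | X].

Univariate covariates (e.g. age, a binary sex indicator) are removed by a
covariate projection directly on their column.  A multicollinear — even
rank-deficient — covariate block (e.g. a lipoprotein profile) is first
compressed to a single predictive target score: a Monte-Carlo-validated
PLS model of the outcome on the block, post-processed by target
projection.  The standardized target score is then projected out like any
univariate covariate, which also adjusts the block's own columns so their
shared variance appears in the variance ledger.

Every projection appends to an orthogonal variance ledger: for each column
the sum of squares removed by each projection step, relative to the
column's sum of squares at the start of the adjustment.  The ledger is the
raw material for variance-partition tables and plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatable import DataTable
from .projection import (
    PLSModel,
    TPModel,
    covariate_project_matrix,
    pls1,
    target_projection,
)
from .validation import ValidationConfig, ValidationResult, monte_carlo_validate

__all__ = [
    "AdjustmentState",
    "CompressionResult",
    "NetModel",
    "NoPredictiveSignalError",
    "compress_multivariate_covariate",
    "adjust_univariate",
    "adjust_multivariate",
    "net_model",
]


class NoPredictiveSignalError(RuntimeError):
    """Monte Carlo validation selected zero predictive components."""


@dataclass
class AdjustmentState:
    """Augmented matrix with the sequence of covariate projections applied.

    ``matrix`` holds the current residuals of [outcome | covariates |
    explanatory | appended scores]; ``original_ss`` the per-column sum of
    squares before any projection (the universal denominator); ``removed_ss``
    one per-column vector per projection label.
    """

    column_names: list[str]
    matrix: np.ndarray
    roles: dict[str, str]
    original_ss: np.ndarray
    projection_sequence: list[tuple[str, str]] = field(default_factory=list)
    removed_ss: dict[str, np.ndarray] = field(default_factory=dict)
    projected_scores: dict[str, np.ndarray] = field(default_factory=dict)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_table(
        cls,
        table: DataTable,
        outcome: str,
        covariates: list[str] | None = None,
        explanatory: list[str] | None = None,
    ) -> "AdjustmentState":
        covariates = covariates if covariates is not None else table.columns_with_role("covariate")
        explanatory = (
            explanatory if explanatory is not None else table.columns_with_role("explanatory")
        )
        names = [outcome] + list(covariates) + list(explanatory)
        idx = [table.index_of(n) for n in names]
        M = table.values[:, idx].astype(float)
        M = M - M.mean(axis=0)  # the projection algebra assumes centered columns
        roles = {outcome: "outcome"}
        roles.update({c: "covariate" for c in covariates})
        roles.update({x: "explanatory" for x in explanatory})
        return cls(
            column_names=names,
            matrix=M,
            roles=roles,
            original_ss=np.sum(M**2, axis=0),
        )

    @classmethod
    def from_arrays(
        cls,
        y: np.ndarray,
        X: np.ndarray,
        Z: np.ndarray | None = None,
        outcome: str = "y",
        covariate_names: list[str] | None = None,
        explanatory_names: list[str] | None = None,
    ) -> "AdjustmentState":
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        X = np.asarray(X, dtype=float)
        blocks = [y]
        names = [outcome]
        roles = {outcome: "outcome"}
        if Z is not None:
            Z = np.asarray(Z, dtype=float)
            covariate_names = covariate_names or [f"z{i + 1}" for i in range(Z.shape[1])]
            blocks.append(Z)
            names += covariate_names
            roles.update({c: "covariate" for c in covariate_names})
        explanatory_names = explanatory_names or [f"x{i + 1}" for i in range(X.shape[1])]
        blocks.append(X)
        names += explanatory_names
        roles.update({x: "explanatory" for x in explanatory_names})
        M = np.hstack(blocks)
        M = M - M.mean(axis=0)
        return cls(
            column_names=names,
            matrix=M,
            roles=roles,
            original_ss=np.sum(M**2, axis=0),
        )

    # -- accessors ---------------------------------------------------------
    @property
    def n_projections(self) -> int:
        return len(self.projection_sequence)

    def index_of(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None

    @property
    def outcome_name(self) -> str:
        return next(n for n in self.column_names if self.roles[n] == "outcome")

    @property
    def explanatory_names(self) -> list[str]:
        return [n for n in self.column_names if self.roles[n] == "explanatory"]

    @property
    def net_y(self) -> np.ndarray:
        return self.matrix[:, self.index_of(self.outcome_name)]

    @property
    def net_X(self) -> np.ndarray:
        idx = [self.index_of(n) for n in self.explanatory_names]
        return self.matrix[:, idx]

    def residual_ss(self) -> np.ndarray:
        return np.sum(self.matrix**2, axis=0)

    def remaining_fraction(self, name: str) -> float:
        j = self.index_of(name)
        return float(self.residual_ss()[j] / self.original_ss[j])

    def copy(self) -> "AdjustmentState":
        return AdjustmentState(
            column_names=list(self.column_names),
            matrix=self.matrix.copy(),
            roles=dict(self.roles),
            original_ss=self.original_ss.copy(),
            projection_sequence=list(self.projection_sequence),
            removed_ss={k: v.copy() for k, v in self.removed_ss.items()},
            projected_scores={k: v.copy() for k, v in self.projected_scores.items()},
        )

    def ledger_rows(self) -> list[dict]:
        """Tidy records: column, projection label, removed SS and fraction."""
        rows = []
        for label, _ in self.projection_sequence:
            removed = self.removed_ss[label]
            for j, name in enumerate(self.column_names):
                denom = self.original_ss[j]
                rows.append(
                    {
                        "column": name,
                        "projection": label,
                        "removed_ss": float(removed[j]),
                        "removed_fraction": float(removed[j] / denom) if denom > 0 else 0.0,
                    }
                )
        return rows

    # -- internal ----------------------------------------------------------
    def _apply_projection(self, col: int, label: str, weight_type: str) -> None:
        ss_before = self.residual_ss()
        z, _, self.matrix = covariate_project_matrix(self.matrix, col)
        removed = ss_before - self.residual_ss()
        self.projection_sequence.append((label, weight_type))
        self.removed_ss[label] = removed
        self.projected_scores[label] = z


def adjust_univariate(state: AdjustmentState, covariate: str) -> AdjustmentState:
    """Project the augmented matrix on one raw covariate column.

    Returns a new state; the input state is not modified.  Re-adjusting a
    covariate whose column has already been zeroed is an error.
    """
    new = state.copy()
    j = new.index_of(covariate)
    if any(label == covariate for label, _ in new.projection_sequence):
        raise ValueError(f"covariate {covariate!r} has already been adjusted for")
    new._apply_projection(j, covariate, "raw column")
    return new


@dataclass
class CompressionResult:
    """A multivariate covariate block condensed to one predictive score."""

    score: np.ndarray  # standardized target score, unit sample variance
    selected_A: int
    pls: PLSModel
    tp: TPModel
    validation: ValidationResult | None

    @property
    def explained_y_fraction(self) -> float:
        return self.pls.explained_y_fraction

    @property
    def explained_block_fraction(self) -> float:
        return self.tp.explained_X_fraction


def compress_multivariate_covariate(
    Z: np.ndarray,
    y: np.ndarray,
    val_config: ValidationConfig | None = None,
    A: int | None = None,
) -> CompressionResult:
    """Condense a (possibly rank-deficient) covariate block to a target score.

    Fits a Monte-Carlo-validated PLS1 model of the outcome on the block,
    post-processes by target projection, and returns the target score
    scaled to unit sample variance.  ``A`` overrides the validated
    component count when given; with ``A`` given and no ``val_config`` the
    resampling step is skipped entirely (useful for population-covariance
    oracles where resampling has no meaning).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if A is not None and val_config is None:
        result = None
    else:
        val_config = val_config or ValidationConfig()
        result = monte_carlo_validate(Z, y, val_config)
    n_comp = A if A is not None else result.selected_A
    if n_comp == 0:
        raise NoPredictiveSignalError(
            "validation selected 0 components: the block carries no "
            "predictive association with the outcome (no mediation signal)"
        )
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    model = pls1(Zc, yc, n_comp)
    tp = target_projection(model, Zc)
    score = tp.score / tp.score.std(ddof=1)
    return CompressionResult(
        score=score,
        selected_A=n_comp,
        pls=model,
        tp=tp,
        validation=result,
    )


def adjust_multivariate(
    state: AdjustmentState,
    score: np.ndarray,
    label: str = "block",
    collinearity_tol: float = 1e-10,
) -> AdjustmentState:
    """Project the augmented matrix on a covariate-block target score.

    The score is appended as a new column of the augmented matrix before
    projection, so the block's own columns are adjusted too and the
    block's variance pattern enters the ledger.  A score collinear with an
    already-projected covariate score is rejected.
    """
    new = state.copy()
    score = np.asarray(score, dtype=float).ravel()
    if score.shape[0] != new.matrix.shape[0]:
        raise ValueError("score length does not match the number of subjects")
    if label in dict(new.projection_sequence):
        raise ValueError(f"projection label {label!r} already used")
    s = score - score.mean()
    for prev_label, z in new.projected_scores.items():
        zz = float(z @ z)
        if zz == 0:
            continue
        r = abs(float(s @ z)) / (np.linalg.norm(s) * np.sqrt(zz))
        if r > 1 - collinearity_tol:
            raise ValueError(
                f"target score is collinear with already-projected covariate "
                f"{prev_label!r} (|r| = {r:.2e} from 1)"
            )
    new.column_names.append(label)
    new.roles[label] = "covariate"
    new.matrix = np.hstack([new.matrix, s.reshape(-1, 1)])
    new.original_ss = np.append(new.original_ss, float(s @ s))
    for k in new.removed_ss:
        new.removed_ss[k] = np.append(new.removed_ss[k], 0.0)
    new._apply_projection(new.matrix.shape[1] - 1, label, "target score")
    return new


@dataclass
class NetModel:
    """Monte-Carlo-validated PLS + target projection on the net data.

    ``pls`` and ``tp`` are None when validation selected zero components
    (a null-model marker: no net predictive association remains).
    """

    validation: ValidationResult | None
    pls: PLSModel | None
    tp: TPModel | None
    state: AdjustmentState

    @property
    def is_null(self) -> bool:
        return self.pls is None

    def explained_y_fraction_of_original(self) -> float:
        """SS of the net fitted outcome over the outcome's original SS."""
        if self.is_null:
            return 0.0
        yhat = self.tp.fitted_y()
        j = self.state.index_of(self.state.outcome_name)
        return float(yhat @ yhat / self.state.original_ss[j])

    def explained_X_fraction_of_original(self, names: list[str] | None = None) -> float:
        """TP-captured SS of chosen explanatory columns over original SS."""
        names = names or self.state.explanatory_names
        if self.is_null:
            return 0.0
        per_var = self.tp.explained_X_per_variable()
        expl_names = self.state.explanatory_names
        captured = sum(per_var[expl_names.index(n)] for n in names)
        denom = sum(
            self.state.original_ss[self.state.index_of(n)] for n in names
        )
        return float(captured / denom)


def net_model(
    state: AdjustmentState,
    val_config: ValidationConfig | None = None,
    A: int | None = None,
) -> NetModel:
    """Fit the net predictive model y_net ~ X_net after all adjustments.

    Runs Monte Carlo validation on the net data, fits PLS1 with the
    selected (or overridden) component count, and target-projects to the
    single net predictive component.  With zero selected components a
    null-model marker is returned instead of raising.  As in the
    compression step, an explicit ``A`` with no ``val_config`` skips the
    resampling.
    """
    X_net = state.net_X
    y_net = state.net_y
    if not np.any(np.sum(X_net**2, axis=0) > 0):
        raise ValueError("no explanatory column with nonzero residual variance")
    if A is not None and val_config is None:
        result = None
    else:
        val_config = val_config or ValidationConfig()
        result = monte_carlo_validate(X_net, y_net, val_config)
    n_comp = A if A is not None else result.selected_A
    if n_comp == 0:
        return NetModel(validation=result, pls=None, tp=None, state=state)
    model = pls1(X_net, y_net, n_comp)
    tp = target_projection(model, X_net)
    return NetModel(validation=result, pls=model, tp=tp, state=state)
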