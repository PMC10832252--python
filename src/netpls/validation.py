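"""Repeated Monte Carlo resampling to choose the number of PLS components.

Each repetition randomly splits the subjects into a calibration half (used
to center, scale, and fit PLS models with 0..A_max components) and a
prediction half on which the cost (RMSEP or MAE) is recorded.  The selected
model is the component count with the lowest median cost, walked downward
while too large a fraction of its cost distribution exceeds the median of
the model with one component less — the exceedance-fraction rule that
protects against overfitting.

The 0-component reference model predicts the calibration mean, so the
comparison "one component less" is defined all the way down to A = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .projection import pls1

__all__ = ["ValidationConfig", "ValidationResult", "monte_carlo_validate", "prediction_cost"]


def prediction_cost(y_true: np.ndarray, y_pred: np.ndarray, cost: str = "RMSEP") -> float:
    """RMSEP (root mean squared prediction error) or MAE of held-out subjects."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty prediction vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    resid = y_true - y_pred
    if cost.upper() == "RMSEP":
        return float(np.sqrt(np.mean(resid**2)))
    if cost.upper() == "MAE":
        return float(np.mean(np.abs(resid)))
    raise ValueError(f"unknown cost {cost!r} (use 'RMSEP' or 'MAE')")


@dataclass
class ValidationConfig:
    """User-tunable knobs of the resampling procedure.

    n_rep : number of random calibration/prediction splits.
    A_max : largest component count examined.
    threshold : exceedance-fraction acceptance limit (must be < 0.5 to
        protect against overfitting in well-conditioned data; exposed as a
        parameter because the appropriate value is problem-dependent).
    split_fraction : fraction of subjects in the calibration half.
    cost : "RMSEP" or "MAE".
    seed : PRNG seed recorded in the result for reproducibility.
    """

    n_rep: int = 1000
    A_max: int = 6
    threshold: float = 0.5
    split_fraction: float = 0.5
    cost: str = "RMSEP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.A_max < 1:
            raise ValueError("A_max must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_rep": self.n_rep,
            "A_max": self.A_max,
            "threshold": self.threshold,
            "split_fraction": self.split_fraction,
            "cost": self.cost,
            "seed": self.seed,
        }


@dataclass
class ValidationResult:
    """Cost distributions per component count and the selected model size."""

    rmsep_samples: np.ndarray  # n_rep x (A_max + 1); column a = a components
    medians: np.ndarray  # length A_max + 1
    exceedance_fractions: np.ndarray  # length A_max; entry a-1 compares a vs a-1
    selected_A: int
    config: ValidationConfig = field(default_factory=ValidationConfig)

    def exceedance(self, a: int) -> float:
        """Fraction of a-component costs exceeding the (a-1)-model median."""
        if not 1 <= a <= self.config.A_max:
            raise ValueError(f"a must be in 1..{self.config.A_max}")
        return float(self.exceedance_fractions[a - 1])

    def to_dict(self) -> dict:
        return {
            "medians": self.medians.tolist(),
            "exceedance_fractions": self.exceedance_fractions.tolist(),
            "selected_A": self.selected_A,
            "config": self.config.to_dict(),
        }


def _split_costs(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    config: ValidationConfig,
) -> np.ndarray:
    """Costs for one random split, for 0..A_max components."""
    n = X.shape[0]
    n_cal = int(np.floor(config.split_fraction * n))
    if config.A_max >= n_cal:
        raise ValueError(
            f"A_max={config.A_max} must be smaller than the calibration size {n_cal}"
        )
    for attempt in range(11):
        idx = rng.choice(n, size=n_cal, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        X_cal, y_cal = X[mask], y[mask]
        X_val, y_val = X[~mask], y[~mask]
        x_sd = X_cal.std(axis=0, ddof=1)
        y_sd = y_cal.std(ddof=1)
        if np.all(x_sd > 0) and y_sd > 0:
            break
        warnings.warn("zero-variance calibration column; resampling split", stacklevel=2)
    else:  # pragma: no cover - requires pathological data
        raise RuntimeError("could not draw a calibration set with nonzero variances")

    x_mean = X_cal.mean(axis=0)
    y_mean = y_cal.mean()
    Xc, yc = (X_cal - x_mean) / x_sd, (y_cal - y_mean) / y_sd
    Xv, yv = (X_val - x_mean) / x_sd, (y_val - y_mean) / y_sd

    costs = np.empty(config.A_max + 1)
    costs[0] = prediction_cost(yv, np.zeros_like(yv), config.cost)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # early exhaustion handled below
        model = pls1(Xc, yc, config.A_max)
    W, P, q = model.latent.weights, model.latent.loadings, model.inner_coefficients
    for a in range(1, config.A_max + 1):
        k = min(a, model.n_components)  # exhausted components reuse the last b
        b_a = W[:, :k] @ solve_triangular(P[:, :k].T @ W[:, :k], q[:k], lower=False)
        costs[a] = prediction_cost(yv, Xv @ b_a, config.cost)
    return costs


def _select(medians: np.ndarray, exceed: np.ndarray, threshold: float) -> int:
    """Lowest-median component count, walked down by the exceedance rule."""
    a_star = int(np.argmin(medians))  # smallest A on exact ties
    while a_star > 0 and exceed[a_star - 1] >= threshold:
        a_star -= 1
    return a_star


def monte_carlo_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: ValidationConfig | None = None,
) -> ValidationResult:
    """Run the repeated-resampling validation and select a component count.

    X and y are the preprocessed full data; each repetition re-centers and
    re-scales using calibration-half statistics only, so no information
    leaks from the prediction half.
    """
    config = config or ValidationConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(config.seed)
    samples = np.empty((config.n_rep, config.A_max + 1))
    for r in range(config.n_rep):
        samples[r] = _split_costs(X, y, rng, config)
    medians = np.median(samples, axis=0)
    exceed = np.array(
        [np.mean(samples[:, a] > medians[a - 1]) for a in range(1, config.A_max + 1)]
    )
    selected = _select(medians, exceed, config.threshold)
    return ValidationResult(
        rmsep_samples=samples,
        medians=medians,
        exceedance_fractions=exceed,
        selected_A=selected,
        config=config,
    )
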