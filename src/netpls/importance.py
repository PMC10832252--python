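"""Variable importance on the target projection: SF and SR.

The selectivity fraction SF_i = ||t_TP p_i,TP||^2 / ||x_i||^2 is the share
of variable i's total variance captured by the target component, signed by
the direction of association (the sign of the loading, with the target
score oriented toward the fitted outcome), so SF ranges over [-1, +1].
The selectivity ratio SR_i divides by the residual variance
||e_i,TP||^2 = ||x_i - t_TP p_i,TP||^2 instead, so SR is nonnegative and
unbounded; numerically infinite ratios are capped at a sentinel and
flagged.  Monte Carlo confidence limits come from refitting the fixed-size
model on repeated random calibration halves and taking empirical
percentiles of the per-variable SF distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import TPModel, pls1, target_projection
from .validation import ValidationConfig

__all__ = [
    "ImportanceProfile",
    "selectivity_fraction",
    "selectivity_ratio",
    "mc_importance_limits",
    "SR_CAP",
]

SR_CAP = 1e6


def selectivity_fraction(tp: TPModel, X: np.ndarray) -> np.ndarray:
    """Signed per-variable selectivity fractions for a fitted TP model."""
    X = np.asarray(X, dtype=float)
    ss = np.sum(X**2, axis=0)
    if np.any(ss == 0):
        zero = np.flatnonzero(ss == 0)
        raise ValueError(f"zero-variance variables at indices {zero.tolist()}")
    captured = tp.explained_X_per_variable()
    sf = captured / ss
    return np.sign(tp.loading) * sf


def selectivity_ratio(tp: TPModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable selectivity ratios; returns (sr, capped flags)."""
    X = np.asarray(X, dtype=float)
    ss = np.sum(X**2, axis=0)
    if np.any(ss == 0):
        zero = np.flatnonzero(ss == 0)
        raise ValueError(f"zero-variance variables at indices {zero.tolist()}")
    resid = X - np.outer(tp.score, tp.loading)
    resid_ss = np.sum(resid**2, axis=0)
    captured = tp.explained_X_per_variable()
    with np.errstate(divide="ignore", over="ignore"):
        sr = np.where(resid_ss > 0, captured / np.where(resid_ss > 0, resid_ss, 1.0), np.inf)
    capped = ~np.isfinite(sr) | (sr > SR_CAP)
    sr = np.where(capped, SR_CAP, sr)
    return sr, capped


@dataclass
class ImportanceProfile:
    """Full-data SF/SR plus Monte Carlo percentile limits per variable."""

    table: pd.DataFrame  # columns: sf, sr, sr_capped, mc_median, mc_low, mc_high
    selected_A: int
    config: ValidationConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="variable")


def mc_importance_limits(
    X: np.ndarray,
    y: np.ndarray,
    selected_A: int,
    config: ValidationConfig | None = None,
    names: list[str] | None = None,
) -> ImportanceProfile:
    """Empirical 2.5/97.5% limits of SF across Monte Carlo resampled models.

    The component count is fixed in advance (from the validation step);
    each repetition refits PLS + TP on a random calibration half,
    centered and scaled by that half's statistics.
    """
    if selected_A < 1:
        raise ValueError("selected_A must be >= 1 (a null model has no importances)")
    config = config or ValidationConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, v = X.shape
    names = names or [f"x{i + 1}" for i in range(v)]
    rng = np.random.default_rng(config.seed)
    n_cal = int(np.floor(config.split_fraction * n))

    sf_samples = np.empty((config.n_rep, v))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # early component exhaustion is fine here
        for r in range(config.n_rep):
            idx = rng.choice(n, size=n_cal, replace=False)
            X_cal = X[idx]
            y_cal = y[idx]
            x_sd = X_cal.std(axis=0, ddof=1)
            x_sd[x_sd == 0] = 1.0
            Xc = (X_cal - X_cal.mean(axis=0)) / x_sd
            yc = y_cal - y_cal.mean()
            model = pls1(Xc, yc, selected_A)
            tp = target_projection(model, Xc)
            sf_samples[r] = selectivity_fraction(tp, Xc)

        Xc_full = X - X.mean(axis=0)
        yc_full = y - y.mean()
        model = pls1(Xc_full, yc_full, selected_A)
        tp = target_projection(model, Xc_full)
        sf = selectivity_fraction(tp, Xc_full)
        sr, capped = selectivity_ratio(tp, Xc_full)

    # empirical (type-7, numpy default linear) percentiles
    low, med, high = np.percentile(sf_samples, [2.5, 50.0, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "sf": sf,
            "sr": sr,
            "sr_capped": capped,
            "mc_median": med,
            "mc_low": low,
            "mc_high": high,
        },
        index=names,
    )
    return ImportanceProfile(table=table, selected_A=selected_A, config=config)
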