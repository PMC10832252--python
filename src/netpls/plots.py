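"""Static renderings of the three core displays.

Variance plot: stacked bars of each variable's variance split among
covariate projections, the net predictive component, and the residual.
Importance plot: signed selectivity fractions with Monte Carlo limits, in
input column order.  Validation plot: median prediction cost against the
number of PLS components with the per-pair exceedance fractions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .importance import ImportanceProfile
from .partition import VariancePartition
from .validation import ValidationResult

__all__ = ["plot_variance_partition", "plot_importance", "plot_validation"]


def plot_variance_partition(
    partition: VariancePartition, path: str | Path, title: str = "Variance pattern"
) -> None:
    df = partition.display()
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(df)), 4))
    bottom = np.zeros(len(df))
    for part in df.columns:
        ax.bar(df.index, df[part].to_numpy(), bottom=bottom, label=part)
        bottom += df[part].to_numpy()
    ax.set_ylabel("fraction of original variance")
    ax.set_title(title)
    ax.legend(fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_importance(
    profile: ImportanceProfile, path: str | Path, title: str = "Selectivity fractions"
) -> None:
    t = profile.table
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(t)), 4))
    yerr = np.vstack(
        [t["mc_median"] - t["mc_low"], t["mc_high"] - t["mc_median"]]
    ).clip(min=0)
    ax.bar(x, t["mc_median"].to_numpy(), yerr=yerr, capsize=2)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(t.index, rotation=90, fontsize=7)
    ax.set_ylabel("selectivity fraction")
    ax.set_ylim(-1, 1)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_validation(
    result: ValidationResult, path: str | Path, title: str = "Component validation"
) -> None:
    a = np.arange(result.medians.size)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(a, result.medians, "k-o", label="median cost")
    star = result.selected_A
    ax.plot([star], [result.medians[star]], "r*", ms=14, label=f"selected A={star}")
    for i, frac in enumerate(result.exceedance_fractions, start=1):
        ax.annotate(f"{frac:.2f}", (i, result.medians[i]), fontsize=7,
                    textcoords="offset points", xytext=(0, 6))
    ax.set_xlabel("number of PLS components")
    ax.set_ylabel(result.config.cost)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
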