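"""Loader and column conventions for the insulin-resistance cohort analysis.

The worked application models HOMA-IR (homeostatic model assessment of
insulin resistance) in 836 children from explanatory lifestyle variables
(3 adiposity measures and a 23-interval physical-activity intensity
spectrum), with age and sex as univariate confounders and a 26-feature
serum lipoprotein profile as a multivariate (rank-deficient) mediator.

The dataset itself is not distributed with this package.  To reproduce the
cohort results, place the published baseline table (post-preprocessing,
pre-adjustment) under ``data/ask_baseline.csv`` (or ``.xlsx``) in the
working tree with one header row and columns, in any order:

* ``homa_ir`` — the outcome;
* ``age`` and ``sex`` (0 = girl, 1 = boy) — confounders;
* ``bmi``, ``wc_height``, ``skinfold`` — adiposity;
* ``pa_01`` .. ``pa_23`` — time in each PA intensity interval;
* 26 lipoprotein columns prefixed ``lp_`` — the mediator block.

All variables except age and sex are log-transformed before the analysis;
every retained column is then centered and scaled to unit variance.
"""

from __future__ import annotations

from pathlib import Path

from .datatable import DataTable, preprocess, read_table

__all__ = ["STUDY_COLUMNS", "load_study_table", "preprocess_study_table"]

STUDY_COLUMNS = {
    "outcome": "homa_ir",
    "confounders": ["age", "sex"],
    "adiposity": ["bmi", "wc_height", "skinfold"],
    "pa": [f"pa_{i + 1:02d}" for i in range(23)],
    "lipoprotein_prefix": "lp_",
}

DEFAULT_LOCATIONS = ("data/ask_baseline.csv", "data/ask_baseline.xlsx")


def load_study_table(path: str | Path | None = None) -> DataTable:
    """Load the cohort baseline table and assign roles.

    Raises FileNotFoundError with placement instructions when the file is
    not available (it must be obtained from the study's published
    supplementary material).
    """
    candidates = [Path(path)] if path is not None else [Path(p) for p in DEFAULT_LOCATIONS]
    found = next((p for p in candidates if p.exists()), None)
    if found is None:
        raise FileNotFoundError(
            "cohort dataset not found (looked for "
            + ", ".join(str(p) for p in candidates)
            + "); place the published baseline table there with the column "
            "layout documented in netpls.study"
        )
    table = read_table(found)
    cols = table.column_names
    lipo = [c for c in cols if c.startswith(STUDY_COLUMNS["lipoprotein_prefix"])]
    expected = (
        [STUDY_COLUMNS["outcome"]]
        + STUDY_COLUMNS["confounders"]
        + STUDY_COLUMNS["adiposity"]
        + STUDY_COLUMNS["pa"]
    )
    missing = [c for c in expected if c not in cols]
    if missing or len(lipo) != 26:
        raise ValueError(
            f"unexpected study layout: missing {missing}, "
            f"{len(lipo)} lipoprotein columns (expected 26)"
        )
    roles = {STUDY_COLUMNS["outcome"]: "outcome"}
    roles.update({c: "covariate" for c in STUDY_COLUMNS["confounders"] + lipo})
    roles.update(
        {c: "explanatory" for c in STUDY_COLUMNS["adiposity"] + STUDY_COLUMNS["pa"]}
    )
    table.set_roles(roles)
    return table


def preprocess_study_table(table: DataTable) -> DataTable:
    """Log-transform everything except age and sex, center, scale."""
    log_cols = [c for c in table.column_names if c not in ("age", "sex")]
    return preprocess(table, log_columns=log_cols, standardize=True)
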