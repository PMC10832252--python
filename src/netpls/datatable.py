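"""Tabular input, validation, preprocessing, and descriptive correlations.

The analysis operates on a named numeric matrix (rows = subjects, columns =
variables) in which every column plays one of four roles: outcome,
explanatory, covariate, or excluded.  Preprocessing follows the standard
chemometric recipe: optional natural-log transform of strictly positive
columns, mean centering, and unit-variance scaling.  Each applied transform
is recorded per column so a raw table can be replayed to the processed one
bit-identically, and the variance of every column *before* any adjustment is
kept as the universal denominator for "percent of original variance"
outputs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json
import numpy as np
import pandas as pd

__all__ = [
    "DataTable",
    "ValidationReport",
    "read_table",
    "from_dataframe",
    "preprocess",
    "correlation_matrix",
]

ROLES = ("outcome", "explanatory", "covariate", "excluded")

_BOOLEAN_TOKENS = {
    "yes": 1.0,
    "no": 0.0,
    "true": 1.0,
    "false": 0.0,
    "1": 1.0,
    "0": 0.0,
}


class TableError(ValueError):
    """Raised for structural problems in an input table."""


@dataclass
class ValidationReport:
    """Names of columns that need attention before modelling."""

    missing: list[str] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.missing and not self.zero_variance


@dataclass
class DataTable:
    """Named numeric matrix with per-column preprocessing provenance.

    Attributes
    ----------
    values : (N, V) float array
        Current data, after whatever transforms ``preprocessing_log`` lists.
    column_names : list of str
        Unique identifiers, in column order.
    column_roles : dict
        Maps each column name to one of ``ROLES``; unset columns default to
        ``"excluded"``.
    preprocessing_log : dict
        Per-column ordered list of applied transforms (``"log"``,
        ``"center"``, ``"scale"``) with the parameters needed to replay them.
    original_variance : dict
        Sample variance (N-1 denominator) of each column before centering or
        scaling.  All variance fractions reported by the package are
        relative to these values.
    """

    values: np.ndarray
    column_names: list[str]
    column_roles: dict[str, str] = field(default_factory=dict)
    preprocessing_log: dict[str, list[dict]] = field(default_factory=dict)
    original_variance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableError("values must be a 2-D matrix")
        if len(self.column_names) != self.values.shape[1]:
            raise TableError("column_names length does not match matrix width")
        if len(set(self.column_names)) != len(self.column_names):
            dupes = sorted(
                {c for c in self.column_names if self.column_names.count(c) > 1}
            )
            raise TableError(f"duplicate column names: {dupes}")
        for name, role in self.column_roles.items():
            if role not in ROLES:
                raise TableError(f"unknown role {role!r} for column {name!r}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def index_of(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index_of(name)]

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.column_names if self.column_roles.get(c) == role]

    def subset(self, names: Sequence[str]) -> "DataTable":
        idx = [self.index_of(n) for n in names]
        return DataTable(
            values=self.values[:, idx].copy(),
            column_names=list(names),
            column_roles={n: self.column_roles.get(n, "excluded") for n in names},
            preprocessing_log={n: list(self.preprocessing_log.get(n, [])) for n in names},
            original_variance={
                n: self.original_variance[n]
                for n in names
                if n in self.original_variance
            },
        )

    def set_roles(self, roles: Mapping[str, str]) -> None:
        for name, role in roles.items():
            if role not in ROLES:
                raise TableError(f"unknown role {role!r}")
            self.index_of(name)
            self.column_roles[name] = role

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def validate(self) -> ValidationReport:
        """Flag (never silently drop) missing-value and invariant columns."""
        report = ValidationReport()
        for j, name in enumerate(self.column_names):
            col = self.values[:, j]
            if np.isnan(col).any():
                report.missing.append(name)
            elif np.var(col) == 0.0:
                report.zero_variance.append(name)
        return report

    # -- provenance --------------------------------------------------------
    def log_sidecar(self) -> str:
        """JSON document carrying the preprocessing log for written outputs."""
        return json.dumps(
            {
                "columns": self.column_names,
                "preprocessing_log": self.preprocessing_log,
                "original_variance": self.original_variance,
            },
            indent=2,
        )

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        path.with_suffix(path.suffix + ".log.json").write_text(self.log_sidecar())


def _coerce_numeric(series: pd.Series, name: str, convert_boolean: bool) -> pd.Series:
    """Convert a raw column to float, recoding recognized boolean tokens."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    if pd.api.types.is_bool_dtype(series):
        return series.astype(float)

    def convert(cell):
        if pd.isna(cell):
            return np.nan
        if isinstance(cell, (int, float, np.integer, np.floating)):
            return float(cell)
        token = str(cell).strip().lower()
        if token == "":
            return np.nan
        if convert_boolean and token in _BOOLEAN_TOKENS:
            return _BOOLEAN_TOKENS[token]
        try:
            return float(token)
        except ValueError:
            raise TableError(
                f"column {name!r}: cell {cell!r} is neither numeric nor a "
                "recognized boolean token (yes/no, true/false, 1/0)"
            ) from None

    return series.map(convert).astype(float)


def from_dataframe(
    df: pd.DataFrame,
    convert_boolean: bool = True,
) -> DataTable:
    """Build a DataTable from a pandas frame, coercing boolean tokens."""
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise TableError(f"duplicate column names: {dupes}")
    cols = {}
    for name in df.columns:
        cols[name] = _coerce_numeric(df[name], str(name), convert_boolean)
    values = np.column_stack([cols[n].to_numpy() for n in df.columns])
    if values.size == 0:
        raise TableError("empty table")
    return DataTable(values=values, column_names=[str(c) for c in df.columns])


def read_table(
    path: str | Path,
    format: str | None = None,
    convert_boolean: bool = True,
    id_column: str | None = None,
    sheet: int | str = 0,
) -> DataTable:
    """Read a CSV or XLSX file into a DataTable with roles unset.

    Parameters
    ----------
    path : path to the file; the first row must be a header of column names.
    format : "csv" or "xlsx"; inferred from the suffix when omitted.
    convert_boolean : recode yes/no, true/false (case-insensitive) to 1/0.
    id_column : optional name of a subject-identifier column to drop.
    sheet : worksheet index or name for xlsx input (first sheet by default).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    else:
        raise TableError(f"unsupported format {format!r}")
    if id_column is not None:
        if id_column not in df.columns:
            raise TableError(f"id column {id_column!r} not found")
        df = df.drop(columns=[id_column])
    return from_dataframe(df, convert_boolean=convert_boolean)


def preprocess(
    table: DataTable,
    log_columns: Iterable[str] = (),
    standardize: bool = True,
) -> DataTable:
    """Log-transform selected columns, then center (and scale) every column.

    The natural log is applied first, only to ``log_columns`` (all entries
    must be strictly positive).  Every column is then mean-centered; with
    ``standardize`` each is additionally scaled to unit sample variance
    (N-1 denominator).  The variance recorded in ``original_variance`` is
    taken after the log step but before centering/scaling, so downstream
    variance fractions refer to the modelling scale.
    """
    log_columns = set(log_columns)
    unknown = log_columns - set(table.column_names)
    if unknown:
        raise TableError(f"log columns not in table: {sorted(unknown)}")
    report = table.validate()
    if report.missing:
        raise TableError(f"missing values in columns: {report.missing}")

    values = table.values.copy()
    log = {n: list(table.preprocessing_log.get(n, [])) for n in table.column_names}
    original_variance = {}
    for j, name in enumerate(table.column_names):
        col = values[:, j]
        if name in log_columns:
            if np.any(col <= 0):
                raise TableError(
                    f"column {name!r} has non-positive entries; cannot log-transform"
                )
            col = np.log(col)
            log[name].append({"op": "log"})
        mean = float(np.mean(col))
        col = col - mean
        log[name].append({"op": "center", "mean": mean})
        var = float(np.sum(col**2) / (len(col) - 1))
        original_variance[name] = var
        if standardize:
            if var == 0.0:
                raise TableError(f"column {name!r} has zero variance; cannot scale")
            col = col / np.sqrt(var)
            log[name].append({"op": "scale", "sd": float(np.sqrt(var))})
        values[:, j] = col

    return DataTable(
        values=values,
        column_names=list(table.column_names),
        column_roles=dict(table.column_roles),
        preprocessing_log=log,
        original_variance=original_variance,
    )


def replay(raw: DataTable, preprocessing_log: Mapping[str, list[dict]]) -> np.ndarray:
    """Re-apply a recorded preprocessing log to a raw table.

    Returns the transformed matrix; used to check provenance determinism.
    """
    values = raw.values.copy()
    for j, name in enumerate(raw.column_names):
        col = values[:, j]
        for step in preprocessing_log.get(name, []):
            if step["op"] == "log":
                col = np.log(col)
            elif step["op"] == "center":
                col = col - step["mean"]
            elif step["op"] == "scale":
                col = col / step["sd"]
            else:  # pragma: no cover - defensive
                raise TableError(f"unknown preprocessing op {step['op']!r}")
        values[:, j] = col
    return values


def correlation_matrix(
    table: DataTable, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix of the selected columns.

    Requires at least two observations and nonzero variance in every
    selected column.
    """
    names = list(columns) if columns is not None else list(table.column_names)
    idx = [table.index_of(n) for n in names]
    sub = table.values[:, idx]
    if sub.shape[0] < 2:
        raise TableError("need at least two observations for correlations")
    sd = sub.std(axis=0)
    zero = [n for n, s in zip(names, sd) if s == 0.0]
    if zero:
        raise TableError(f"zero-variance columns in correlation request: {zero}")
    corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=names, columns=names)
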