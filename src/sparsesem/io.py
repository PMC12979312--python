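"""Delimited-matrix input/output and the standardization convention.

Every estimator in this package works on *standardized* data: each column is
mean-centered and scaled so that its squared norm equals the number of cases N
(population-variance scaling, i.e. ``std(ddof=0)``).  This convention is chosen
deliberately: the factor-score columns are constrained to squared norm N, so
with this scaling the total sum of squares is ``N * J`` exactly and, for the
orthogonal cardinality-constrained variant, nonzero loadings coincide with
item-score Pearson correlations.

Missing values are rejected, not imputed; impute externally before analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MatrixFormatError",
    "MatrixParseError",
    "MissingDataError",
    "DegenerateVariableError",
    "StandardizationRecord",
    "load_matrix",
    "write_matrix",
    "standardize",
]


class MatrixFormatError(ValueError):
    """Raised for structurally broken input (ragged rows, empty file)."""


class MatrixParseError(ValueError):
    """Raised when a cell cannot be parsed as a number."""


class MissingDataError(ValueError):
    """Raised when the input contains missing cells (no missing-data support)."""


class DegenerateVariableError(ValueError):
    """Raised when a variable has zero variance and cannot be standardized."""


_MISSING_TOKENS = {"", "na", "n/a", "nan", "null", "none", "."}


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-variable centering/scaling applied to a raw matrix.

    Applying ``(x - mean) / scale`` column-wise to the raw data reproduces the
    standardized matrix; :meth:`inverse` undoes it.
    """

    means: np.ndarray
    scales: np.ndarray

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.means) / self.scales

    def inverse(self, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized, dtype=float) * self.scales + self.means


def load_matrix(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a cases x variables matrix from delimited text with a header row.

    Parameters
    ----------
    path : path-like
        File with one header row of variable names and one case per row.
    delimiter : str
        Field separator (``","`` for CSV, ``"\\t"`` for TSV).

    Returns
    -------
    pandas.DataFrame
        Float matrix, columns named from the header.

    Raises
    ------
    MatrixFormatError
        Empty file or ragged rows.
    MatrixParseError
        A non-numeric cell (the error names its row and column).
    MissingDataError
        Any empty/NA cell; imputation is out of scope.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        rows = list(csv.reader(handle, delimiter=delimiter))
    if not rows:
        raise MatrixFormatError(f"{path}: file is empty")
    header = [name.strip() for name in rows[0]]
    n_var = len(header)
    body = rows[1:]
    if not body:
        raise MatrixFormatError(f"{path}: no data rows below the header")
    values = np.empty((len(body), n_var), dtype=float)
    for i, row in enumerate(body):
        if len(row) != n_var:
            raise MatrixFormatError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {n_var}"
            )
        for j, cell in enumerate(row):
            token = cell.strip()
            if token.lower() in _MISSING_TOKENS:
                raise MissingDataError(
                    f"{path}: missing value at row {i + 2}, column '{header[j]}'"
                    " - no missing-data support; impute before loading"
                )
            try:
                value = float(token)
            except ValueError as exc:
                raise MatrixParseError(
                    f"{path}: non-numeric value {token!r} at row {i + 2},"
                    f" column '{header[j]}'"
                ) from exc
            if np.isnan(value):
                raise MissingDataError(
                    f"{path}: missing value at row {i + 2}, column '{header[j]}'"
                )
            values[i, j] = value
    return pd.DataFrame(values, columns=header)


def write_matrix(data, path, delimiter: str = ",") -> None:
    """Write a matrix (DataFrame or array) as delimited text with a header."""
    frame = (
        data
        if isinstance(data, pd.DataFrame)
        else pd.DataFrame(np.asarray(data, dtype=float))
    )
    frame.to_csv(path, sep=delimiter, index=False)


def standardize(data):
    """Center and scale each column to mean 0 and squared norm N.

    Uses the population standard deviation (denominator N), so that
    ``sum(y_ij**2) == N`` per column and ``||Y||_F**2 == N * J`` exactly.
    Idempotent to numerical tolerance.

    Returns
    -------
    (standardized, record)
        ``standardized`` has the same container type as the input
        (DataFrame in, DataFrame out); ``record`` is a
        :class:`StandardizationRecord`.

    Raises
    ------
    DegenerateVariableError
        If some column is constant.
    """
    is_frame = isinstance(data, pd.DataFrame)
    values = np.asarray(data, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D cases x variables matrix")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cases to standardize")
    means = values.mean(axis=0)
    centered = values - means
    scales = np.sqrt(np.mean(centered**2, axis=0))
    floor = 1e-12 * np.maximum(1.0, np.abs(means))
    degenerate = np.flatnonzero(scales <= floor)
    if degenerate.size:
        names = (
            [str(data.columns[j]) for j in degenerate]
            if is_frame
            else [f"column {j}" for j in degenerate]
        )
        raise DegenerateVariableError(
            "constant column(s) cannot be standardized: " + ", ".join(names)
        )
    out = centered / scales
    record = StandardizationRecord(means=means, scales=scales)
    if is_frame:
        out = pd.DataFrame(out, columns=data.columns, index=data.index)
    return out, record
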