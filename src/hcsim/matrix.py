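"""Expression-matrix container and delimited-text I/O.

The canonical in-memory orientation is samples x variables.  Files on disk
commonly store genes (variables) as rows, so the loader accepts either
orientation and transposes to canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input matrix violates the loader's contract."""


@dataclass
class ExpressionMatrix:
    """A samples x variables real matrix with row and column identifiers.

    Parameters
    ----------
    values
        Dense float array of shape (n_samples, n_variables).
    sample_ids, variable_ids
        Unique string identifiers for rows and columns.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variable_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression matrix must be 2-dimensional")
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if not self.variable_ids:
            self.variable_ids = [f"V{j + 1}" for j in range(m)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match row count")
        if len(self.variable_ids) != m:
            raise ValidationError("variable_ids length does not match column count")
        if len(set(self.variable_ids)) != m:
            raise ValidationError("variable_ids must be unique")
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def variances(self, ddof: int = 1) -> np.ndarray:
        """Per-variable sample variance."""
        return self.values.var(axis=0, ddof=ddof)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_ids
        )


def read_expression_matrix(
    path: str | Path,
    orientation: str = "variables_in_rows",
    delimiter: str = "\t",
    impute_mean: bool = False,
) -> ExpressionMatrix:
    """Read a delimited numeric matrix with one id row and one id column.

    Parameters
    ----------
    orientation
        ``"variables_in_rows"`` (genes as rows, the common omics layout) or
        ``"samples_in_rows"``.
    impute_mean
        Replace missing cells by the per-variable mean instead of rejecting.
    """
    if orientation not in ("variables_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if orientation == "samples_in_rows":
        # variable ids live in the header, which pandas de-duplicates
        # silently ("g1", "g1.1") — check the raw tokens instead
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(delimiter)[1:]
        if len(set(header)) != len(header):
            raise ValidationError(f"duplicate variable ids in header of {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = _locate_non_numeric(df)
        raise ValidationError(
            f"non-numeric cell at row {bad[0]!r}, column {bad[1]!r} in {path}"
        ) from exc
    if orientation == "variables_in_rows":
        df = df.T
    if df.isna().any().any():
        if impute_mean:
            df = df.fillna(df.mean(axis=0))
        else:
            raise ValidationError(
                f"{path} contains missing values (pass impute_mean=True to fill)"
            )
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=list(df.index.astype(str)),
        variable_ids=list(df.columns.astype(str)),
    )


def _locate_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return str(df.index[bad.argmax()]), str(col)
    return "?", "?"


def write_expression_matrix(
    X: ExpressionMatrix,
    path: str | Path,
    orientation: str = "variables_in_rows",
    delimiter: str = "\t",
) -> None:
    """Write the matrix back to delimited text (inverse of the reader)."""
    df = X.to_frame()
    if orientation == "variables_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def matrix_from_values(
    values: np.ndarray, variable_ids: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Wrap a raw samples x variables array, autogenerating ids if absent."""
    return ExpressionMatrix(
        values=np.asarray(values, dtype=float),
        variable_ids=list(variable_ids) if variable_ids is not None else [],
    )
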