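"""The gene-by-sample expression container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

State = Literal["raw_counts", "log_normalized"]


@dataclass
class ExpressionMatrix:
    """A genes × samples numeric matrix with per-sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
    state : {"raw_counts", "log_normalized"}
        ``raw_counts`` requires non-negative integers; ``log_normalized``
        holds log2-scale intensities.
    annotations : pandas.DataFrame, optional
        One row per sample (index = sample ids); typical columns are
        ``group`` (STIC/NOSTIC), ``subtype``, ``tissue``, ``origin``.
    """

    values: pd.DataFrame
    state: State = "raw_counts"
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy()
        if np.any(~np.isfinite(arr)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.state == "raw_counts":
            if np.any(arr < 0):
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integers")
        elif self.state != "log_normalized":
            raise ValueError(f"unknown state: {self.state!r}")
        if self.annotations is not None:
            missing = self.annotations.index.symmetric_difference(v.columns)
            if len(missing):
                raise ValueError(
                    f"annotations do not match sample ids (mismatch: {list(missing)[:5]})"
                )
            # keep annotation rows in matrix column order
            self.annotations = self.annotations.loc[v.columns]

    # -- convenience ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], state=self.state, annotations=self.annotations
        )

    def annotation(self, column: str) -> pd.Series:
        if self.annotations is None or column not in self.annotations:
            raise KeyError(f"annotation column {column!r} not available")
        return self.annotations[column]
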