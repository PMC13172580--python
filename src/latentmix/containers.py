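"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a genes x samples numeric
matrix carrying identifiers and a scale tag so that downstream stages can
assert they are fed data on the scale they expect (raw counts vs. log2
size-factor-normalized vs. CPM-log vs. z-scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognized scale tags for :class:`ExpressionMatrix`.
SCALES = ("counts", "log2norm", "cpmlog", "zscore", "abundance")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix with identifiers and a scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with sample ids as columns.
    scale:
        One of ``counts``, ``log2norm``, ``cpmlog``, ``zscore`` or
        ``abundance`` (the last one for metabolite/protein matrices, which
        are the only matrices allowed to carry missing values).
    """

    data: pd.DataFrame
    scale: str = "counts"
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag: {self.scale!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if not self.allow_missing and not np.all(np.isfinite(values)):
            raise ValueError("non-finite values in expression matrix")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row subset preserving order of `genes`; unknown ids raise KeyError."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale,
                                self.allow_missing)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale, self.allow_missing)


@dataclass
class SampleTable:
    """Per-sample metadata aligned with a paired :class:`ExpressionMatrix`.

    Columns follow brain-bank conventions: diagnosis, batch, RIN, PMI, sex,
    education, age_baseline, age_death, cohort, region; subgroup labels and
    scores may be attached after discovery.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        if not self.data.index.equals(matrix.sample_ids):
            raise ValueError("sample table does not match expression matrix")
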