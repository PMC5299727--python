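"""Labelled count and covariate tables.

The two containers here are thin, validated wrappers around numpy arrays
with sample/column labels, mirroring how a taxa abundance table (samples x
taxa, non-negative integer counts) and a design matrix (samples x
covariates, reals) travel together through the fitting pipeline.  TSV
round-tripping goes through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TaxaCountTable", "CovariateTable"]


@dataclass
class TaxaCountTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        ``(n, J)`` array of non-negative integers, one row per sample.
    sample_ids
        ``n`` sample labels.
    taxon_ids
        ``J`` unique taxon labels.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    row_totals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValueError(
                    f"non-integer count at sample {bad[0]}, taxon {bad[1]}"
                )
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(f"negative count at sample {bad[0]}, taxon {bad[1]}")
        n, J = self.counts.shape
        if J < 2:
            raise ValueError("need at least two taxa")
        if n < 1:
            raise ValueError("need at least one sample")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != n or len(self.taxon_ids) != J:
            raise ValueError("label lengths do not match the count matrix")
        if len(set(self.taxon_ids)) != J:
            raise ValueError("taxon labels must be unique")
        self.row_totals = self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.taxon_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TaxaCountTable":
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxaCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.map(lambda v: not isinstance(v, (int, np.integer, float))).to_numpy()
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-numeric count at sample {df.index[r]!r}, taxon {df.columns[c]!r} in {path}"
            )
        if np.any(arr != np.floor(arr)):
            r, c = np.argwhere(arr != np.floor(arr))[0]
            raise ValueError(
                f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r} in {path}"
            )
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r} in {path}"
            )
        return cls.from_dataframe(df)


@dataclass
class CovariateTable:
    """Samples x covariates design matrix of reals.

    ``standardized`` records whether columns have been centred to mean zero
    and scaled to unit sample variance (n-1 denominator).
    """

    values: np.ndarray
    covariate_ids: list[str]
    sample_ids: list[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x covariates matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate values must be finite")
        n, P = self.values.shape
        self.covariate_ids = [str(c) for c in self.covariate_ids]
        if len(self.covariate_ids) != P:
            raise ValueError("covariate label length does not match the matrix")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise ValueError("sample label length does not match the matrix")
        if self.standardized:
            mu = self.values.mean(axis=0)
            sd2 = self.values.var(axis=0, ddof=1) if n > 1 else np.ones(P)
            if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(sd2 - 1.0) > 1e-8):
                raise ValueError("standardized flag set but columns are not standardized")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids is not None else range(self.n_samples)
        return pd.DataFrame(
            self.values, index=pd.Index(idx, name="sample_id"), columns=self.covariate_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "CovariateTable":
        return cls(
            df.to_numpy(dtype=np.float64),
            list(df.columns.astype(str)),
            sample_ids=list(df.index.astype(str)),
            standardized=standardized,
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CovariateTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))


def check_paired(Y: TaxaCountTable, X: CovariateTable) -> None:
    """Raise if the two tables do not describe the same samples."""
    if Y.n_samples != X.n_samples:
        raise ValueError(
            f"count table has {Y.n_samples} samples but covariate table has {X.n_samples}"
        )
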