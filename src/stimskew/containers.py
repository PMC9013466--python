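"""Core in-memory containers for the pipeline.

The canonical orientation throughout the functional API is genes x samples
(rows are genes), matching how count matrices are distributed on disk.  The
scikit-learn estimator classes accept the transposed samples x genes layout,
following the sklearn convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "NormFactors", "DEGTable_COLUMNS", "validate_deg_table"]

#: Required columns of a differential-expression result table (a DataFrame
#: indexed by gene id).
DEGTable_COLUMNS = ("log2fc", "pvalue", "fdr", "mean_expr", "significant")


@dataclass
class CountMatrix:
    """Gene-level count matrix with per-sample metadata.

    Parameters
    ----------
    counts : pd.DataFrame
        Non-negative integer counts, genes (rows) x samples (columns).
    sample_meta : pd.DataFrame
        Indexed by sample id; must contain a ``group`` column and may
        contain a ``study`` column.  Must cover every sample in ``counts``.
    gene_lengths : pd.Series, optional
        Positive transcript/gene lengths in bp, indexed by gene id.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta must contain a 'group' column")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        # keep metadata aligned to the count columns
        self.sample_meta = self.sample_meta.loc[self.counts.columns]
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
                raise ValueError("gene_lengths must be positive and cover all genes")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[gene_ids],
            self.sample_meta,
            None if self.gene_lengths is None else self.gene_lengths.loc[gene_ids],
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)],
            self.sample_meta.loc[list(sample_ids)],
            self.gene_lengths,
        )


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scale factors.

    ``effective_size = library_size * tmm_factor``; the TMM factors are
    rescaled so their geometric mean over samples is 1.
    """

    library_size: pd.Series
    tmm_factor: pd.Series

    def __post_init__(self) -> None:
        if (self.library_size <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.tmm_factor <= 0).any():
            raise ValueError("TMM factors must be positive")
        logf = np.log(self.tmm_factor.to_numpy(dtype=float))
        if abs(logf.mean()) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def validate_deg_table(deg: pd.DataFrame) -> pd.DataFrame:
    """Check that ``deg`` has the DEGTable schema and valid ranges."""
    for col in DEGTable_COLUMNS:
        if col not in deg.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    if ((deg["pvalue"] < 0) | (deg["pvalue"] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if ((deg["fdr"] < 0) | (deg["fdr"] > 1)).any():
        raise ValueError("FDR values outside [0, 1]")
    return deg
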