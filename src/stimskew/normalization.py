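"""Count filtering and TMM / CPM / FPKM normalization.

TMM (trimmed mean of M-values) computes one positive scale factor per
sample from precision-weighted, doubly trimmed log2 expression ratios to a
reference sample; factors are rescaled to geometric mean 1 so that the
effective library size is ``library_size * factor``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import CountMatrix, NormFactors

__all__ = [
    "filter_low_counts",
    "tmm_factors",
    "cpm",
    "fpkm",
    "TMMNormalizer",
]


def filter_low_counts(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Drop genes with primarily zero/low counts.

    A gene is retained when its library-size CPM is >= ``min_cpm`` in at
    least ``min_samples`` samples (default: the smallest group size).
    Sample set and gene order are preserved.
    """
    if min_samples is None:
        min_samples = int(cm.groups.value_counts().min())
    if min_samples > cm.n_samples:
        raise ValueError("min_samples exceeds the number of samples")
    lib = cm.counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = cm.sample_ids[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    raw_cpm = cm.counts.to_numpy(dtype=float) / lib * 1e6
    keep = (raw_cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("no genes pass the low-count filter")
    return cm.subset_genes(cm.gene_ids[keep])


def _tmm_one(
    y: np.ndarray,
    yr: np.ndarray,
    n: float,
    nr: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (both 1-D counts)."""
    pos = (y > 0) & (yr > 0)
    if not pos.any():
        warnings.warn("no genes shared with the reference sample; factor set to 1")
        return 1.0
    p, pr = y[pos] / n, yr[pos] / nr
    m = np.log2(p / pr)
    a = 0.5 * np.log2(p * pr)
    # binomial variance approximation -> precision weights, expressed
    # through the count proportions only so that rescaling a sample's
    # counts leaves the factors (hence all CPM values) exactly unchanged
    w = (1 - p) / p + (1 - pr) / pr
    finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w) & (w > 0)
    m, a, w = m[finite], a[finite], w[finite]
    ng = m.size
    if ng == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m, hi_m = np.floor(ng * trim_m) + 1, ng - np.floor(ng * trim_m)
    lo_a, hi_a = np.floor(ng * trim_a) + 1, ng - np.floor(ng * trim_a)
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors for every sample.

    Reference sample defaults to the one whose upper-quartile count
    fraction is closest to the mean upper quartile over samples.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = cm.sample_ids[lib <= 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    if ref_sample is None:
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(len(lib))])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = cm.sample_ids.get_loc(ref_sample)
    yr, nr = counts[:, ref_idx], lib[ref_idx]
    f = np.array(
        [
            1.0 if j == ref_idx else _tmm_one(counts[:, j], yr, lib[j], nr, trim_m, trim_a)
            for j in range(len(lib))
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(
        library_size=pd.Series(lib, index=cm.sample_ids, name="library_size"),
        tmm_factor=pd.Series(f, index=cm.sample_ids, name="tmm_factor"),
    )


def cpm(
    cm: CountMatrix,
    nf: NormFactors | None = None,
    log_scale: bool = False,
    pseudo: float = 0.0,
) -> pd.DataFrame:
    """Counts per million over the TMM-effective library size.

    ``value = count / effective_size * 1e6``; with ``log_scale`` the result
    is ``log2(value + pseudo)`` (``pseudo`` must then be positive).
    """
    if nf is None:
        nf = tmm_factors(cm)
    eff = nf.effective_size.loc[cm.sample_ids].to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")
    vals = cm.counts.to_numpy(dtype=float) / eff * 1e6
    if log_scale:
        if pseudo <= 0:
            raise ValueError("pseudo must be > 0 for log-scale CPM")
        vals = np.log2(vals + pseudo)
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)


def fpkm(cm: CountMatrix, nf: NormFactors | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million: CPM additionally divided by
    gene length in kb.  Requires ``cm.gene_lengths``."""
    if cm.gene_lengths is None:
        raise ValueError("FPKM requires gene lengths")
    base = cpm(cm, nf=nf, log_scale=False)
    return base.div(cm.gene_lengths / 1e3, axis=0)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """TMM normalization as a scikit-learn transformer.

    ``X`` follows the sklearn layout, samples x genes.  ``fit`` learns
    per-sample library sizes and TMM factors from the fitted matrix itself
    (normalization is per-sample, so transform only accepts the fitted X);
    ``transform`` returns (log-)CPM.

    Parameters
    ----------
    trim_m, trim_a : float
        Two-sided trim fractions on M- and A-values.
    log : bool
        Return log2(CPM + pseudo) instead of linear CPM.
    pseudo : float
        Additive constant for the log transform.
    """

    def __init__(
        self,
        trim_m: float = 0.30,
        trim_a: float = 0.05,
        log: bool = False,
        pseudo: float = 0.125,
    ):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.log = log
        self.pseudo = pseudo

    def _as_count_matrix(self, X) -> CountMatrix:
        X = check_array(X, dtype=float)
        counts = pd.DataFrame(
            X.T,
            index=[f"g{i}" for i in range(X.shape[1])],
            columns=[f"s{j}" for j in range(X.shape[0])],
        )
        meta = pd.DataFrame({"group": ["all"] * X.shape[0]}, index=counts.columns)
        return CountMatrix(counts, meta)

    def fit(self, X, y=None):
        cm = self._as_count_matrix(X)
        nf = tmm_factors(cm, trim_m=self.trim_m, trim_a=self.trim_a)
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0])
        self.library_sizes_ = nf.library_size.to_numpy()
        self.norm_factors_ = nf.tmm_factor.to_numpy()
        self.effective_sizes_ = nf.effective_size.to_numpy()
        return self

    def transform(self, X):
        check_is_fitted(self, "norm_factors_")
        X = check_array(X, dtype=float)
        if X.shape[0] != len(self.effective_sizes_):
            raise ValueError("TMM factors are per-sample; transform the fitted matrix")
        vals = X / self.effective_sizes_[:, None] * 1e6
        if self.log:
            vals = np.log2(vals + self.pseudo)
        return vals
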