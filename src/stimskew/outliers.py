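"""PCA-based outlier screening of samples.

Samples are projected with PCA on the gene-centered log-expression matrix;
a sample is flagged when its distance to its group centroid in the first
two components exceeds median + 3*MAD of all within-group distances.
Flags are advisory only: nothing is dropped automatically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.decomposition import PCA

__all__ = ["pca_outlier_screen"]


def pca_outlier_screen(
    logexpr: pd.DataFrame,
    n_components: int = 2,
    groups=None,
):
    """Screen samples for outliers in PCA space.

    Parameters
    ----------
    logexpr : pd.DataFrame
        Log-scale expression, genes x samples.
    n_components : int
        Number of components to report (>= 2 used for flagging).
    groups : array-like, optional
        Group label per sample; all samples form one group if omitted.

    Returns
    -------
    coords : pd.DataFrame, samples x components ("PC1", ...)
    variance_fractions : np.ndarray, non-increasing, sums to <= 1
    flags : pd.Series of bool per sample
    """
    samples = logexpr.columns
    n = len(samples)
    if n < 3:
        raise ValueError("need >= 3 samples for outlier screening")
    if n_components > n:
        raise ValueError("more components requested than samples")
    X = logexpr.to_numpy(dtype=float).T  # samples x genes; PCA centers genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    varfrac = pca.explained_variance_ratio_

    groups = np.asarray(["all"] * n if groups is None else groups)
    use = coords[:, : min(2, n_components)]
    dist = np.empty(n)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        centroid = use[idx].mean(axis=0)
        dist[idx] = np.linalg.norm(use[idx] - centroid, axis=1)
    cutoff = np.median(dist) + 3.0 * median_abs_deviation(dist)
    flags = dist > cutoff
    coords_df = pd.DataFrame(
        coords, index=samples, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return coords_df, varfrac, pd.Series(flags, index=samples, name="outlier")
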