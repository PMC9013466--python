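"""Negative-binomial two-group differential expression.

The model is NB with mean mu and variance mu + phi*mu^2.  Dispersion phi is
estimated by conditional maximum likelihood pooled over genes (common phi)
and shrunk per-gene toward the common value with a fixed prior weight
(tagwise phi).  The two-group test is exact: library sizes are equalized by
quantile-adjusting counts to a common effective size, and conditional on
the per-gene total the case-group sum follows a Beta-Binomial(t, n1/phi,
n2/phi) law (Binomial(t, n1/(n1+n2)) in the Poisson limit); the two-sided
p-value sums the probabilities of all splits no more likely than the one
observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormFactors
from .normalization import cpm, tmm_factors

__all__ = [
    "DispersionEstimate",
    "bh_adjust",
    "estimate_dispersion",
    "nb_exact_test",
    "NBExactTest",
]

_PHI_MIN = 1e-6
_POISSON_PHI = 1e-8  # below this, use the Poisson limit


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DispersionEstimate:
    """Common and per-gene (tagwise) NB dispersions."""

    common: float
    tagwise: pd.Series
    prior_weight: float

    def __post_init__(self) -> None:
        if self.common < 0 or (self.tagwise < 0).any():
            raise ValueError("dispersions must be non-negative")


# ---------------------------------------------------------------------------
# conditional (replicate-permutation-invariant) NB likelihood
# ---------------------------------------------------------------------------


def _cond_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray], phi: float) -> np.ndarray:
    """Per-gene conditional NB log-likelihood at dispersion ``phi``.

    ``pseudo`` is genes x samples at a common library size.  For a group of
    n replicates with counts y_j and total z the conditional log-likelihood
    is  sum_j lgamma(y_j + r) + lgamma(n r) - lgamma(z + n r) - n lgamma(r)
    with r = 1/phi; summed over groups.
    """
    r = 1.0 / max(phi, _PHI_MIN)
    ll = np.zeros(pseudo.shape[0])
    for idx in group_idx:
        y = pseudo[:, idx]
        n = len(idx)
        if n < 2:
            continue  # a single replicate carries no conditional information
        z = y.sum(axis=1)
        ll += (
            gammaln(y + r).sum(axis=1)
            + gammaln(n * r)
            - gammaln(z + n * r)
            - n * gammaln(r)
        )
    return ll


def _equalize_counts(
    counts: np.ndarray,
    eff_sizes: np.ndarray,
    group_of: np.ndarray,
    phi: float,
) -> tuple[np.ndarray, float]:
    """Quantile-adjust counts to the geometric-mean effective size.

    Each count is mapped through its fitted NB CDF (midpoint-corrected) to
    the matching continuous quantile of the NB with the same per-group
    abundance at the common size, so that samples become exchangeable.
    Returns (pseudo counts, common size).
    """
    common = float(np.exp(np.mean(np.log(eff_sizes))))
    if np.max(np.abs(eff_sizes - common)) / common < 1e-12:
        return counts.astype(float), common

    pseudo = np.empty_like(counts, dtype=float)
    groups = np.unique(group_of)
    for g in groups:
        idx = np.where(group_of == g)[0]
        tot = counts[:, idx].sum(axis=1)
        prop = tot / eff_sizes[idx].sum()  # per-gene abundance in this group
        for j in idx:
            m_in = prop * eff_sizes[j]
            m_out = prop * common
            pseudo[:, j] = _q2q_nbinom(counts[:, j], m_in, m_out, phi)
    return np.clip(pseudo, 0.0, None), common


def _q2q_nbinom(y: np.ndarray, m_in: np.ndarray, m_out: np.ndarray, phi: float) -> np.ndarray:
    """Continuous quantile-to-quantile NB map; identity when m_in == m_out."""
    out = y.astype(float)
    ok = (m_in > 0) & (m_out > 0)
    if not ok.any():
        return out
    yv, mi, mo = y[ok], m_in[ok], m_out[ok]
    if phi < _POISSON_PHI:
        cdf_prev = poisson.cdf(yv - 1, mi)
        pmf_obs = poisson.pmf(yv, mi)
        u = np.clip(cdf_prev + 0.5 * pmf_obs, 1e-12, 1 - 1e-12)
        k = poisson.ppf(u, mo)
        cdf_km1 = poisson.cdf(k - 1, mo)
        pmf_k = poisson.pmf(k, mo)
    else:
        r = 1.0 / phi
        p_in = r / (r + mi)
        p_out = r / (r + mo)
        cdf_prev = nbinom.cdf(yv - 1, r, p_in)
        pmf_obs = nbinom.pmf(yv, r, p_in)
        u = np.clip(cdf_prev + 0.5 * pmf_obs, 1e-12, 1 - 1e-12)
        k = nbinom.ppf(u, r, p_out)
        cdf_km1 = nbinom.cdf(k - 1, r, p_out)
        pmf_k = nbinom.pmf(k, r, p_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(pmf_k > 1e-300, (u - cdf_km1) / pmf_k, 0.5)
    out[ok] = k + np.clip(frac, 0.0, 1.0) - 0.5
    return out


def estimate_dispersion(
    cm: CountMatrix,
    groups=None,
    nf: NormFactors | None = None,
    prior_weight: float = 10.0,
    phi_max: float = 10.0,
    n_iter: int = 2,
) -> DispersionEstimate:
    """Common + tagwise NB dispersion by conditional maximum likelihood.

    The common phi maximizes the conditional likelihood pooled over genes
    (library sizes equalized first; the equalization and the estimate are
    alternated ``n_iter`` times).  Tagwise phi_g maximizes the per-gene
    conditional likelihood plus ``prior_weight`` times the genewise-average
    likelihood, so phi_g shrinks to the common value as the weight grows.
    """
    groups = np.asarray(cm.groups if groups is None else groups)
    labels, counts_per = np.unique(groups, return_counts=True)
    if len(labels) < 2 and counts_per.max() < 2:
        raise ValueError("need >= 2 groups or replicated samples to estimate dispersion")
    if (counts_per >= 2).sum() == 0:
        raise ValueError("no group has >= 2 replicates; no residual degrees of freedom")
    if nf is None:
        nf = tmm_factors(cm)
    counts = cm.counts.to_numpy(dtype=float)
    eff = nf.effective_size.loc[cm.sample_ids].to_numpy(dtype=float)

    phi = 0.1
    pseudo = counts
    for _ in range(max(n_iter, 1)):
        pseudo, _ = _equalize_counts(counts, eff, groups, phi)
        gidx = [np.where(groups == g)[0] for g in labels]

        def neg_pooled(logphi: float) -> float:
            return -float(_cond_loglik(pseudo, gidx, float(np.exp(logphi))).sum())

        res = minimize_scalar(
            neg_pooled,
            bounds=(np.log(_PHI_MIN), np.log(phi_max)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        phi = float(np.exp(res.x))

    # tagwise: grid search including the common value so the infinite-prior
    # limit lands exactly on the common estimate
    grid = np.unique(np.concatenate([np.geomspace(1e-4, phi_max, 40), [phi]]))
    ll = np.column_stack([_cond_loglik(pseudo, gidx, g) for g in grid])
    llbar = ll.mean(axis=0)
    tag_idx = np.argmax(ll + prior_weight * llbar, axis=1)
    tagwise = pd.Series(grid[tag_idx], index=cm.gene_ids, name="tagwise_phi")
    return DispersionEstimate(common=phi, tagwise=tagwise, prior_weight=prior_weight)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def _double_tail_p(s1: int, t: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p: total mass of splits no more likely than (s1, t-s1).

    Conditional law of the case-group sum given the total t is
    Beta-Binomial(t, n1/phi, n2/phi); Binomial(t, n1/(n1+n2)) when phi -> 0.
    """
    if t == 0:
        return 1.0
    # canonical orientation so that swapping group labels yields the exact
    # same floating-point computation (p is invariant under the swap)
    if (n1, s1) > (n2, t - s1):
        s1, n1, n2 = t - s1, n2, n1
    k = np.arange(t + 1)
    lc = gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)
    if phi < _POISSON_PHI:
        q = n1 / (n1 + n2)
        logp = lc + k * np.log(q) + (t - k) * np.log1p(-q)
    else:
        a, b = n1 / phi, n2 / phi
        logp = (
            lc
            + gammaln(k + a)
            + gammaln(t - k + b)
            - gammaln(t + a + b)
            + gammaln(a + b)
            - gammaln(a)
            - gammaln(b)
        )
    logp -= logsumexp(logp)
    obs = logp[s1]
    return float(min(1.0, np.exp(logsumexp(logp[logp <= obs + 1e-10]))))


def nb_exact_test(
    cm: CountMatrix,
    nf: NormFactors | None = None,
    disp: DispersionEstimate | None = None,
    case: str = None,
    control: str = None,
    alpha: float = 0.05,
    pseudo: float = 0.125,
) -> pd.DataFrame:
    """Exact NB test of ``case`` vs ``control``; returns a DEG table.

    The reported log2fc is the pseudocount fold-change of TMM-normalized
    group-mean CPM (``log2((mean_case + pseudo)/(mean_control + pseudo))``),
    mean_expr is the average log2(CPM + pseudo) over the tested samples,
    and ``significant`` flags BH-FDR <= alpha.
    """
    groups = cm.groups
    for g in (case, control):
        if g not in set(groups):
            raise ValueError(f"unknown group label: {g!r}")
    if nf is None:
        nf = tmm_factors(cm)
    if disp is None:
        disp = estimate_dispersion(cm, nf=nf)

    keep = groups.isin([case, control])
    sub = cm.subset_samples(cm.sample_ids[keep])
    sub_groups = sub.groups.to_numpy()
    eff = nf.effective_size.loc[sub.sample_ids].to_numpy(dtype=float)
    counts = sub.counts.to_numpy(dtype=float)

    # equalize library sizes, pooling the two groups for the abundance
    pooled = np.zeros(len(sub_groups), dtype=int)
    pseudo_counts, _ = _equalize_counts(counts, eff, pooled, disp.common)
    case_idx = np.where(sub_groups == case)[0]
    ctrl_idx = np.where(sub_groups == control)[0]
    n1, n2 = len(case_idx), len(ctrl_idx)
    s1 = np.rint(pseudo_counts[:, case_idx].sum(axis=1)).astype(np.int64)
    s2 = np.rint(pseudo_counts[:, ctrl_idx].sum(axis=1)).astype(np.int64)

    phig = disp.tagwise.loc[cm.gene_ids].to_numpy(dtype=float)
    pvals = np.array(
        [
            _double_tail_p(int(a), int(a + b), n1, n2, float(ph))
            for a, b, ph in zip(s1, s2, phig)
        ]
    )

    expr = cpm(cm, nf)[sub.sample_ids]
    mean_case = expr.iloc[:, case_idx].mean(axis=1)
    mean_ctrl = expr.iloc[:, ctrl_idx].mean(axis=1)
    log2fc = np.log2((mean_case + pseudo) / (mean_ctrl + pseudo))
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "mean_expr": np.log2(expr + pseudo).mean(axis=1),
            "significant": fdr <= alpha,
        },
        index=cm.gene_ids,
    )


class NBExactTest(BaseEstimator):
    """Two-group NB exact test as a scikit-learn style estimator.

    ``fit(X, y)`` takes counts in sklearn layout (samples x genes) and a
    group label per sample; results are exposed as fitted attributes.

    Parameters
    ----------
    case, control : str, optional
        Group labels to contrast.  Default: first unique label in ``y`` is
        the control, second the case.
    alpha : float
        BH-FDR significance cutoff.
    pseudo : float
        Additive constant for the fold-change on normalized reads.
    prior_weight : float
        Shrinkage weight of the tagwise dispersion toward the common one.

    Attributes
    ----------
    results_ : pd.DataFrame
        Per-gene log2fc / pvalue / fdr / mean_expr / significant.
    dispersion_ : DispersionEstimate
    norm_factors_ : NormFactors
    """

    def __init__(
        self,
        case: str | None = None,
        control: str | None = None,
        alpha: float = 0.05,
        pseudo: float = 0.125,
        prior_weight: float = 10.0,
    ):
        self.case = case
        self.control = control
        self.alpha = alpha
        self.pseudo = pseudo
        self.prior_weight = prior_weight

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of samples")
        labels = pd.unique(y)
        if len(labels) < 2:
            raise ValueError("y must contain at least two group labels")
        control = self.control if self.control is not None else labels[0]
        case = self.case if self.case is not None else [l for l in labels if l != control][0]
        counts = pd.DataFrame(
            X.T,
            index=[f"g{i}" for i in range(X.shape[1])],
            columns=[f"s{j}" for j in range(X.shape[0])],
        )
        meta = pd.DataFrame({"group": y}, index=counts.columns)
        cm = CountMatrix(counts, meta)
        nf = tmm_factors(cm)
        disp = estimate_dispersion(cm, nf=nf, prior_weight=self.prior_weight)
        self.norm_factors_ = nf
        self.dispersion_ = disp
        self.results_ = nb_exact_test(
            cm, nf, disp, case=case, control=control, alpha=self.alpha, pseudo=self.pseudo
        )
        self.n_features_in_ = X.shape[1]
        return self
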