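"""Cross-study meta-analysis of differential expression.

Each study is processed independently (filtering, TMM, NB exact test per
comparison); genes recurrently significant across comparisons are
selected; log-expression is Z-scored per gene within each study to remove
study-level batch effects before the combined matrix is clustered
hierarchically into co-regulation clusters, summarized by their median
pseudocount log2 fold-change per comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .containers import CountMatrix, NormFactors
from .classify import pseudo_fc
from .diffexpr import estimate_dispersion, nb_exact_test
from .normalization import cpm, filter_low_counts, tmm_factors

__all__ = [
    "Study",
    "StudySet",
    "ClusterTable",
    "per_study_deg",
    "select_recurrent_genes",
    "zscore_within_study",
    "cluster_genes",
    "cluster_median_fc",
    "set_overlap_share",
    "WithinStudyScaler",
    "CoRegulationClusterer",
]


@dataclass
class Study:
    name: str
    counts: CountMatrix
    comparisons: list  # list of (case, control) group labels

    def __post_init__(self) -> None:
        groups = set(self.counts.groups)
        for case, control in self.comparisons:
            if case not in groups or control not in groups:
                raise ValueError(
                    f"study {self.name!r}: comparison ({case!r}, {control!r}) "
                    "references an undefined group"
                )


@dataclass
class StudySet:
    """A collection of case/control studies sharing one gene universe.

    If the studies' gene sets differ, the intersection is taken with a
    warning and every matrix is subset to it.
    """

    studies: list

    def __post_init__(self) -> None:
        names = [s.name for s in self.studies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate study names")
        if len(self.studies) < 1:
            raise ValueError("empty study set")
        common = self.studies[0].counts.gene_ids
        for s in self.studies[1:]:
            common = common.intersection(s.counts.gene_ids)
        dropped = sum(len(s.counts.gene_ids) - len(common) for s in self.studies)
        if dropped:
            warnings.warn(
                f"gene universes differ across studies; intersecting to "
                f"{len(common)} genes ({dropped} gene rows dropped)"
            )
            self.studies = [
                Study(s.name, s.counts.subset_genes(common), s.comparisons)
                for s in self.studies
            ]

    @property
    def comparisons(self) -> list:
        """All (study, case, control) triples in declaration order."""
        return [
            (s.name, case, control)
            for s in self.studies
            for case, control in s.comparisons
        ]


def per_study_deg(
    ss: StudySet,
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    pseudo: float = 0.125,
    prior_weight: float = 10.0,
) -> dict:
    """Filter, normalize and test every comparison of every study.

    Processing is fully independent per study (one filtered/normalized
    matrix shared by that study's comparisons).  Returns a mapping
    ``(study, case, control) -> DEG table``.
    """
    out = {}
    for s in ss.studies:
        cm = filter_low_counts(s.counts, min_cpm=min_cpm)
        nf = tmm_factors(cm)
        disp = estimate_dispersion(cm, nf=nf, prior_weight=prior_weight)
        for case, control in s.comparisons:
            n_case = int((cm.groups == case).sum())
            n_ctrl = int((cm.groups == control).sum())
            if min(n_case, n_ctrl) < 2:
                raise ValueError(
                    f"study {s.name!r}, comparison ({case!r}, {control!r}): "
                    "fewer than 2 replicates on one side"
                )
            out[(s.name, case, control)] = nb_exact_test(
                cm, nf, disp, case=case, control=control, alpha=alpha, pseudo=pseudo
            )
    return out


def select_recurrent_genes(deg_tables: dict, min_comparisons: int = 4) -> list:
    """Genes significant in at least ``min_comparisons`` comparisons.

    Genes absent from a table (filtered out in that study) count as not
    significant there.  Order is stable: first appearance across tables.
    """
    if min_comparisons > len(deg_tables):
        raise ValueError("min_comparisons exceeds the number of comparisons")
    order: list = []
    seen = set()
    for deg in deg_tables.values():
        for g in deg.index:
            if g not in seen:
                seen.add(g)
                order.append(g)
    hits = pd.Series(0, index=pd.Index(order))
    for deg in deg_tables.values():
        sig = deg.index[deg["significant"]]
        hits.loc[hits.index.intersection(sig)] += 1
    return [g for g in order if hits[g] >= min_comparisons]


def zscore_within_study(expr: pd.DataFrame, study_labels) -> pd.DataFrame:
    """Standardize each gene within each study (mean 0, sd 1, ddof=1).

    ``expr`` is genes x samples on the normalized log scale.  A gene that
    is constant within a study maps to zeros there.  Any per-study
    constant offset (batch effect) is removed exactly.
    """
    study_labels = pd.Series(np.asarray(study_labels), index=expr.columns)
    z = pd.DataFrame(index=expr.index, columns=expr.columns, dtype=float)
    for study, cols in study_labels.groupby(study_labels).groups.items():
        block = expr[list(cols)].to_numpy(dtype=float)
        if block.shape[1] < 2:
            raise ValueError(f"study {study!r} has fewer than 2 samples")
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            zb = (block - mu) / sd
        zb[np.broadcast_to(sd == 0, zb.shape)] = 0.0
        z[list(cols)] = zb
    return z


@dataclass
class ClusterTable:
    """Gene -> co-regulation cluster assignment plus the linkage tree."""

    labels: pd.Series  # gene_id -> cluster id in 1..k
    linkage: np.ndarray = field(repr=False, default=None)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster_id: int) -> list:
        return self.labels.index[self.labels == cluster_id].tolist()


def cluster_genes(
    zm: pd.DataFrame,
    k: int = 22,
    linkage: str = "complete",
    distance: str = "euclidean",
) -> ClusterTable:
    """Agglomerative clustering of gene rows cut into exactly k clusters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > zm.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({zm.shape[0]})")
    Z = scipy_linkage(zm.to_numpy(dtype=float), method=linkage, metric=distance)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterTable(pd.Series(labels, index=zm.index, name="cluster"), Z)


def cluster_median_fc(
    ss: StudySet,
    ct: ClusterTable,
    pseudo: float = 0.125,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median pseudocount log2 fold-change of each cluster per comparison.

    Gene-level fold-changes compare TMM-normalized group-mean CPM of each
    case group with its control, with the additive constant ``pseudo``.
    Returns (cluster x comparison medians, gene x comparison table); an
    even member count uses midpoint interpolation (``numpy.median``).
    """
    genes = ct.labels.index
    fc_cols = {}
    for s in ss.studies:
        present = genes.intersection(s.counts.gene_ids)
        if len(present) < len(genes):
            missing = genes.difference(s.counts.gene_ids)
            raise ValueError(
                f"study {s.name!r} lacks {len(missing)} clustered genes"
            )
        nf = tmm_factors(s.counts)
        expr = cpm(s.counts, nf)
        means = expr.T.groupby(s.counts.groups).mean().T
        for case, control in s.comparisons:
            name = f"{s.name}:{case}_vs_{control}"
            fc_cols[name] = pd.Series(
                pseudo_fc(means.loc[genes, case], means.loc[genes, control], pseudo),
                index=genes,
            )
    gene_fc = pd.DataFrame(fc_cols)
    medians = gene_fc.groupby(ct.labels).median()
    medians.index.name = "cluster"
    return medians, gene_fc


def set_overlap_share(cluster_genes, reference_genes) -> float:
    """100 * |cluster & reference| / |cluster|, to one decimal."""
    cluster = set(cluster_genes)
    if not cluster:
        raise ValueError("empty cluster gene set")
    return round(100.0 * len(cluster & set(reference_genes)) / len(cluster), 1)


class WithinStudyScaler(BaseEstimator, TransformerMixin):
    """Per-feature, per-study standardization (sklearn layout).

    ``fit(X, y)`` takes X as samples x genes and ``y`` as the per-sample
    study label; ``transform`` standardizes every gene within every study
    to mean 0 / sd 1 (ddof=1), zeroing constant genes.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.studies_ = np.asarray(y)
        if X.shape[0] != len(self.studies_):
            raise ValueError("X and study labels disagree on sample count")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        expr = pd.DataFrame(X.T)
        z = zscore_within_study(expr, self.studies_)
        return z.to_numpy().T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)


class CoRegulationClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical co-regulation clustering with a fixed cut.

    ``fit(X)`` treats rows of X as gene profiles (for this estimator the
    "samples" are genes); exposes ``labels_`` in 1..n_clusters and the
    scipy ``linkage_`` matrix.
    """

    def __init__(self, n_clusters: int = 22, linkage: str = "complete",
                 metric: str = "euclidean"):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ct = cluster_genes(
            pd.DataFrame(X), k=self.n_clusters, linkage=self.linkage,
            distance=self.metric,
        )
        self.labels_ = ct.labels.to_numpy()
        self.linkage_ = ct.linkage
        self.n_features_in_ = X.shape[1]
        return self
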