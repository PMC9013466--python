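"""Two-way analysis: core vs stimulus-skewed gene classification.

Given three aligned two-group contrasts — stimulus 1 vs control, stimulus
2 vs control and stimulus 1 vs stimulus 2 — each gene is assigned one of
four mutually exclusive categories:

* ``CORE``           — significant vs control under both stimuli, same
                       direction, with no significant difference between
                       the two stimulated conditions;
* ``STIM1_SKEWED``   — regulated only by stimulus 1, or by both with a
                       significant between-stimulus difference and the
                       larger response to stimulus 1, or up under stimulus
                       1 while down under stimulus 2;
* ``STIM2_SKEWED``   — symmetric to the above;
* ``NOT_REGULATED``  — everything else.

Fold-changes are pseudocount log2 ratios of normalized group means, with
the additive constant 0.125 keeping every ratio finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CountMatrix
from .diffexpr import estimate_dispersion, nb_exact_test
from .normalization import cpm, tmm_factors

__all__ = [
    "CORE",
    "STIM1_SKEWED",
    "STIM2_SKEWED",
    "NOT_REGULATED",
    "ContrastTriplet",
    "pseudo_fc",
    "twoway_universe",
    "classify_gene",
    "classify_all",
    "classify_counts",
    "category_counts",
    "category_share",
    "TwoWaySkewClassifier",
]

CORE = "CORE"
STIM1_SKEWED = "STIM1_SKEWED"
STIM2_SKEWED = "STIM2_SKEWED"
NOT_REGULATED = "NOT_REGULATED"


def pseudo_fc(mean_case, mean_control, pseudo: float = 0.125):
    """log2((mean_case + pseudo) / (mean_control + pseudo)); always finite."""
    mean_case = np.asarray(mean_case, dtype=float)
    mean_control = np.asarray(mean_control, dtype=float)
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    if (mean_case < 0).any() or (mean_control < 0).any():
        raise ValueError("normalized means must be non-negative")
    out = np.log2((mean_case + pseudo) / (mean_control + pseudo))
    return float(out) if out.ndim == 0 else out


@dataclass
class ContrastTriplet:
    """Aligned DEG tables for (stim1 vs control, stim2 vs control,
    stim1 vs stim2) plus normalized group-mean expression.

    ``group_means`` is genes x groups (control + both stimuli) on the
    normalized (linear CPM) scale; the classifier derives its plotted
    fold-changes from these with the pseudocount.
    """

    deg1: pd.DataFrame  # stim1 vs control
    deg2: pd.DataFrame  # stim2 vs control
    deg12: pd.DataFrame  # stim1 vs stim2
    group_means: pd.DataFrame
    control: str = "control"
    stim1: str = "IL-6"
    stim2: str = "IFN-a"
    pseudo: float = 0.125
    fc1: pd.Series = field(init=False)
    fc2: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        idx = self.deg1.index
        if not (idx.equals(self.deg2.index) and idx.equals(self.deg12.index)):
            raise ValueError("the three DEG tables must cover identical genes in order")
        for g in (self.control, self.stim1, self.stim2):
            if g not in self.group_means.columns:
                raise ValueError(f"group_means lacks a column for group {g!r}")
        gm = self.group_means.loc[idx]
        self.fc1 = pd.Series(
            pseudo_fc(gm[self.stim1], gm[self.control], self.pseudo), index=idx
        )
        self.fc2 = pd.Series(
            pseudo_fc(gm[self.stim2], gm[self.control], self.pseudo), index=idx
        )

    @property
    def gene_ids(self) -> pd.Index:
        return self.deg1.index


def twoway_universe(triplet: ContrastTriplet, min_abs_log2fc: float = 1.0) -> pd.Index:
    """Genes at least ``2**min_abs_log2fc``-fold significantly regulated in
    either vs-control contrast (the plotted two-way universe)."""
    in1 = triplet.deg1["significant"] & (triplet.fc1.abs() >= min_abs_log2fc)
    in2 = triplet.deg2["significant"] & (triplet.fc2.abs() >= min_abs_log2fc)
    return triplet.gene_ids[in1 | in2]


def classify_gene(
    sig1: bool,
    dir1: int,
    sig2: bool,
    dir2: int,
    sig12: bool,
    absfc1: float,
    absfc2: float,
) -> str:
    """Classify one gene from its contrast flags.

    Parameters are the significance flag and direction (+1/-1) of each
    vs-control contrast, the significance of the between-stimulus
    contrast, and the fold-change magnitudes vs control.

    Decision table: neither significant -> NOT_REGULATED; one significant
    -> that stimulus' skew; both significant with opposite directions ->
    skewed toward the upregulating stimulus; both same direction -> CORE
    unless the between-stimulus contrast is significant, in which case the
    stimulus with the larger |log2FC| wins (an exact magnitude tie falls
    back to CORE with a warning).
    """
    if sig1 and dir1 not in (-1, 1):
        raise ValueError("sig1 set but dir1 is not +1/-1")
    if sig2 and dir2 not in (-1, 1):
        raise ValueError("sig2 set but dir2 is not +1/-1")
    if absfc1 < 0 or absfc2 < 0:
        raise ValueError("fold-change magnitudes must be >= 0")
    if not sig1 and not sig2:
        return NOT_REGULATED
    if sig1 and not sig2:
        return STIM1_SKEWED
    if sig2 and not sig1:
        return STIM2_SKEWED
    if dir1 != dir2:  # discordant: up-stimulus takes the gene, never CORE
        return STIM1_SKEWED if dir1 > 0 else STIM2_SKEWED
    if not sig12:
        return CORE
    if absfc1 > absfc2:
        return STIM1_SKEWED
    if absfc2 > absfc1:
        return STIM2_SKEWED
    warnings.warn(
        "gene significant in both contrasts and between stimuli with exactly "
        "tied magnitudes; classifying as CORE"
    )
    return CORE


def classify_all(
    triplet: ContrastTriplet,
    restrict_to_universe: bool = True,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Apply :func:`classify_gene` to every gene of the triplet.

    Returns a CategoryTable: gene-indexed DataFrame with ``category``,
    ``direction`` (+1/-1/0, the sign of the driving contrast) and the
    two-way plot coordinates ``log2fc_stim1`` / ``log2fc_stim2``.
    """
    idx = triplet.gene_ids
    sig1 = triplet.deg1["significant"].to_numpy()
    sig2 = triplet.deg2["significant"].to_numpy()
    sig12 = triplet.deg12["significant"].to_numpy()
    fc1 = triplet.fc1.to_numpy()
    fc2 = triplet.fc2.to_numpy()
    dir1 = np.sign(fc1).astype(int)
    dir2 = np.sign(fc2).astype(int)
    # a significant contrast with an exactly zero pseudocount fold-change
    # can only arise from identical group means; treat it as up for the
    # direction argument (it cannot influence any magnitude comparison)
    dir1[sig1 & (dir1 == 0)] = 1
    dir2[sig2 & (dir2 == 0)] = 1

    if restrict_to_universe:
        universe = set(twoway_universe(triplet, min_abs_log2fc))
    else:
        universe = set(idx)

    cats = []
    for i, g in enumerate(idx):
        if g not in universe:
            cats.append(NOT_REGULATED)
            continue
        cats.append(
            classify_gene(
                bool(sig1[i]), int(dir1[i]), bool(sig2[i]), int(dir2[i]),
                bool(sig12[i]), abs(fc1[i]), abs(fc2[i]),
            )
        )
    cats = np.array(cats)
    direction = np.zeros(len(idx), dtype=int)
    direction[cats == CORE] = dir1[cats == CORE]
    direction[cats == STIM1_SKEWED] = dir1[cats == STIM1_SKEWED]
    direction[cats == STIM2_SKEWED] = dir2[cats == STIM2_SKEWED]
    return pd.DataFrame(
        {
            "category": cats,
            "direction": direction,
            "log2fc_stim1": fc1,
            "log2fc_stim2": fc2,
        },
        index=idx,
    )


def category_counts(table: pd.DataFrame) -> dict:
    """Counts of each category split by direction (up/down)."""
    out = {}
    for cat in (CORE, STIM1_SKEWED, STIM2_SKEWED):
        sub = table[table["category"] == cat]
        out[f"{cat}_up"] = int((sub["direction"] > 0).sum())
        out[f"{cat}_down"] = int((sub["direction"] < 0).sum())
    out[NOT_REGULATED] = int((table["category"] == NOT_REGULATED).sum())
    return out


def category_share(
    n_core_up: int, n_core_down: int, n_skew_up: int, n_skew_down: int
) -> float:
    """Percentage of a stimulus' regulated genes that belong to the core
    response, to one decimal: 100 * core / (core + skewed)."""
    for n in (n_core_up, n_core_down, n_skew_up, n_skew_down):
        if n < 0:
            raise ValueError("counts must be non-negative")
    total = n_core_up + n_core_down + n_skew_up + n_skew_down
    if total == 0:
        raise ValueError("no regulated genes: share undefined")
    return round(100.0 * (n_core_up + n_core_down) / total, 1)


class TwoWaySkewClassifier(BaseEstimator):
    """End-to-end three-group analysis as a scikit-learn style estimator.

    ``fit(X, y)`` takes counts (samples x genes) and per-sample group
    labels containing ``control``, ``stim1`` and ``stim2``; it runs the
    three NB exact-test contrasts and the two-way classification.

    Attributes
    ----------
    categories_ : pd.DataFrame
        CategoryTable (category, direction, plot coordinates).
    triplet_ : ContrastTriplet
    summary_ : dict
        Per-category counts by direction plus the two core shares.
    """

    def __init__(
        self,
        control: str = "control",
        stim1: str = "stim1",
        stim2: str = "stim2",
        alpha: float = 0.05,
        pseudo: float = 0.125,
        min_abs_log2fc: float = 1.0,
        restrict_to_universe: bool = True,
        prior_weight: float = 10.0,
    ):
        self.control = control
        self.stim1 = stim1
        self.stim2 = stim2
        self.alpha = alpha
        self.pseudo = pseudo
        self.min_abs_log2fc = min_abs_log2fc
        self.restrict_to_universe = restrict_to_universe
        self.prior_weight = prior_weight

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        counts = pd.DataFrame(
            X.T,
            index=[f"g{i}" for i in range(X.shape[1])],
            columns=[f"s{j}" for j in range(X.shape[0])],
        )
        meta = pd.DataFrame({"group": y}, index=counts.columns)
        cm = CountMatrix(counts, meta)
        self.categories_, self.triplet_ = classify_counts(
            cm,
            control=self.control,
            stim1=self.stim1,
            stim2=self.stim2,
            alpha=self.alpha,
            pseudo=self.pseudo,
            min_abs_log2fc=self.min_abs_log2fc,
            restrict_to_universe=self.restrict_to_universe,
            prior_weight=self.prior_weight,
        )
        counts_by = category_counts(self.categories_)
        self.summary_ = counts_by | {
            "core_share_vs_stim1": _safe_share(counts_by, STIM1_SKEWED),
            "core_share_vs_stim2": _safe_share(counts_by, STIM2_SKEWED),
        }
        self.n_features_in_ = X.shape[1]
        return self


def _safe_share(c: dict, skew_key: str) -> float | None:
    try:
        return category_share(
            c["CORE_up"], c["CORE_down"], c[f"{skew_key}_up"], c[f"{skew_key}_down"]
        )
    except ValueError:
        return None


def classify_counts(
    cm: CountMatrix,
    control: str,
    stim1: str,
    stim2: str,
    alpha: float = 0.05,
    pseudo: float = 0.125,
    min_abs_log2fc: float = 1.0,
    restrict_to_universe: bool = True,
    prior_weight: float = 10.0,
) -> tuple[pd.DataFrame, ContrastTriplet]:
    """Run the three contrasts on a three-group count matrix and classify.

    Normalization and dispersion are estimated once on the full matrix, as
    for a single-study design; returns (CategoryTable, ContrastTriplet).
    """
    nf = tmm_factors(cm)
    disp = estimate_dispersion(cm, nf=nf, prior_weight=prior_weight)
    deg1 = nb_exact_test(cm, nf, disp, case=stim1, control=control, alpha=alpha, pseudo=pseudo)
    deg2 = nb_exact_test(cm, nf, disp, case=stim2, control=control, alpha=alpha, pseudo=pseudo)
    deg12 = nb_exact_test(cm, nf, disp, case=stim1, control=stim2, alpha=alpha, pseudo=pseudo)
    expr = cpm(cm, nf)
    means = expr.T.groupby(cm.groups).mean().T
    triplet = ContrastTriplet(
        deg1, deg2, deg12, means, control=control, stim1=stim1, stim2=stim2, pseudo=pseudo
    )
    table = classify_all(
        triplet, restrict_to_universe=restrict_to_universe, min_abs_log2fc=min_abs_log2fc
    )
    return table, triplet
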