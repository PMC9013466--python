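"""Seeded end-to-end evaluation experiments on synthetic data.

These drive the whole pipeline against the simulators' planted ground
truth: type-I-error calibration on all-null data, recovery of planted
core/skewed categories, and recovery of planted co-regulation clusters
(partition agreement plus median fold-change fidelity) across studies
with batch effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .classify import CORE, NOT_REGULATED, STIM1_SKEWED, STIM2_SKEWED, classify_counts
from .meta import (
    Study,
    StudySet,
    cluster_genes,
    cluster_median_fc,
    per_study_deg,
    select_recurrent_genes,
    zscore_within_study,
)
from .normalization import cpm, filter_low_counts, tmm_factors
from .simulate import MetaSimulationConfig, SimulationConfig, simulate_multistudy, simulate_three_group

__all__ = [
    "null_calibration",
    "category_recovery",
    "meta_cluster_recovery",
    "TRUTH_TO_LABEL",
]

#: planted simulator category -> (classifier label, direction)
TRUTH_TO_LABEL = {
    "core_up": (CORE, 1),
    "core_down": (CORE, -1),
    "stim1_up": (STIM1_SKEWED, 1),
    "stim1_down": (STIM1_SKEWED, -1),
    "stim2_up": (STIM2_SKEWED, 1),
    "stim2_down": (STIM2_SKEWED, -1),
}


def null_calibration(
    n_seeds: int = 20,
    n_genes: int = 2000,
    n_per_group: int = 5,
    dispersion: float = 0.1,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Type-I-error calibration of the exact test on all-null data.

    Simulates ``n_seeds`` all-null three-group datasets, runs the full
    three-contrast classification and reports the mean fraction of raw
    p-values below ``alpha`` in the first contrast, the mean empirical
    false-discovery proportion at BH-FDR <= alpha, and the mean fraction
    of genes labelled NOT_REGULATED.
    """
    frac_p, frac_unreg, fdp = [], [], []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            seed=base_seed + s,
            n_genes=n_genes,
            dispersion=dispersion,
            category_fractions={},
            groups=(("control", n_per_group), ("stim1", n_per_group), ("stim2", n_per_group)),
        )
        cm, _ = simulate_three_group(cfg)
        cm = filter_low_counts(cm)
        table, triplet = classify_counts(cm, "control", "stim1", "stim2", alpha=alpha)
        frac_p.append(float((triplet.deg1["pvalue"] < alpha).mean()))
        n_disc = int(triplet.deg1["significant"].sum())
        fdp.append(n_disc / max(n_disc, 1) if n_disc else 0.0)  # all-null: every call false
        frac_unreg.append(float((table["category"] == NOT_REGULATED).mean()))
    return {
        "mean_frac_p_below_alpha": float(np.mean(frac_p)),
        "mean_frac_not_regulated": float(np.mean(frac_unreg)),
        "mean_false_discovery_proportion": float(np.mean(fdp)),
        "per_seed_frac_p": frac_p,
        "n_genes": n_genes,
        "n_seeds": n_seeds,
    }


def category_recovery(
    n_seeds: int = 10,
    n_genes: int = 2000,
    n_per_group: int = 3,
    dispersion: float = 0.1,
    effect_log2fc: float = 2.0,
    base_seed: int = 100,
) -> dict:
    """Recovery of planted core/skewed categories by the classifier.

    Returns per-category mean recovery (fraction of planted genes that
    receive their planted label and direction) over seeds, plus the
    minimum across categories.
    """
    per_cat: dict = {c: [] for c in TRUTH_TO_LABEL}
    for s in range(n_seeds):
        cfg = SimulationConfig(
            seed=base_seed + s,
            n_genes=n_genes,
            dispersion=dispersion,
            effect_log2fc=effect_log2fc,
            groups=(("control", n_per_group), ("stim1", n_per_group), ("stim2", n_per_group)),
        )
        cm, truth = simulate_three_group(cfg)
        cm = filter_low_counts(cm)
        table, _ = classify_counts(cm, "control", "stim1", "stim2")
        tr = truth.loc[table.index]
        for cat, (label, direction) in TRUTH_TO_LABEL.items():
            planted_ids = truth.index[truth["category"] == cat]
            hit = (
                (table.reindex(planted_ids)["category"] == label)
                & (table.reindex(planted_ids)["direction"] == direction)
            )
            # genes removed by the low-count filter count as misses
            per_cat[cat].append(float(hit.fillna(False).sum()) / len(planted_ids))
    means = {cat: float(np.mean(v)) for cat, v in per_cat.items()}
    return {
        "per_category": means,
        "min_recovery": float(min(means.values())),
        "mean_recovery": float(np.mean(list(means.values()))),
        "n_seeds": n_seeds,
        "n_genes": n_genes,
    }


def _default_meta_config(seed: int, n_genes: int = 1000) -> MetaSimulationConfig:
    comps = ["A:case_vs_control", "B:case_vs_control", "C:case_vs_control"]
    vectors = [
        (2, 2, 2),
        (-2, -2, -2),
        (2, -2, 2),
        (-2, 2, 2),
        (2, 2, -2),
    ]
    cluster_defs = [
        (i + 1, 40, dict(zip(comps, v))) for i, v in enumerate(vectors)
    ]
    return MetaSimulationConfig(
        studies=[
            ("A", [("case", "control")], 5),
            ("B", [("case", "control")], 5),
            ("C", [("case", "control")], 5),
        ],
        cluster_defs=cluster_defs,
        n_genes=n_genes,
        study_batch_sd=1.0,
        seed=seed,
    )


def meta_cluster_recovery(
    n_seeds: int = 10,
    n_genes: int = 1000,
    k: int = 5,
    min_comparisons: int = 3,
    pseudo: float = 0.125,
    base_seed: int = 200,
) -> dict:
    """Recovery of five planted co-regulation clusters across three studies.

    For each seed: per-study DE, recurrent-gene selection, within-study
    Z-scoring, clustering at ``k``, adjusted Rand index against the
    planted partition, the worst per-cluster median log2FC error against
    the planted vectors, and an exact batch-invariance check of the
    Z-matrix and the clustering under per-study log-expression offsets.
    """
    aris, fc_errors, batch_ok = [], [], []
    for s in range(n_seeds):
        cfg = _default_meta_config(base_seed + s, n_genes=n_genes)
        studies, truth = simulate_multistudy(cfg)
        ss = StudySet([Study(n, c, cp) for n, c, cp in studies])
        degs = per_study_deg(ss, pseudo=pseudo)
        genes = select_recurrent_genes(degs, min_comparisons=min_comparisons)

        blocks, labels = [], []
        for st in ss.studies:
            cmf = filter_low_counts(st.counts)
            nf = tmm_factors(cmf)
            expr = cpm(cmf, nf, log_scale=True, pseudo=pseudo)
            blocks.append(expr.reindex(genes))
            labels.extend([st.name] * expr.shape[1])
        logexpr = pd.concat(blocks, axis=1).fillna(np.log2(pseudo))
        zm = zscore_within_study(logexpr, labels)
        ct = cluster_genes(zm, k=k)

        # batch invariance: per-study (per-gene) offsets change nothing
        rng = np.random.default_rng(base_seed + s)
        shifted = logexpr.copy()
        lab = np.asarray(labels)
        for st_name in np.unique(lab):
            cols = logexpr.columns[lab == st_name]
            shifted[cols] = shifted[cols].add(
                pd.Series(rng.normal(0, 2, len(genes)), index=logexpr.index), axis=0
            )
        zm2 = zscore_within_study(shifted, labels)
        ct2 = cluster_genes(zm2, k=k)
        batch_ok.append(
            bool(
                np.allclose(zm.to_numpy(), zm2.to_numpy(), atol=1e-9)
                and (ct.labels == ct2.labels).all()
            )
        )

        truth_cluster = truth.loc[genes, "cluster"]
        planted_mask = truth_cluster.notna()
        aris.append(
            float(
                adjusted_rand_score(
                    truth_cluster[planted_mask].astype(int),
                    ct.labels[planted_mask.to_numpy()],
                )
            )
        )

        medians, _ = cluster_median_fc(ss, ct, pseudo=pseudo)
        fc_cols = [f"log2fc_{c}" for c in cfg.comparison_names]
        worst = 0.0
        for c in medians.index:
            members = ct.members(c)
            planted_vec = truth.loc[members, fc_cols].median()
            worst = max(worst, float(np.max(np.abs(medians.loc[c].to_numpy() - planted_vec.to_numpy()))))
        fc_errors.append(worst)
    return {
        "mean_ari": float(np.mean(aris)),
        "max_median_fc_error": float(np.max(fc_errors)),
        "mean_median_fc_error": float(np.mean(fc_errors)),
        "batch_invariant_all_seeds": bool(all(batch_ok)),
        "n_seeds": n_seeds,
        "n_genes": n_genes,
    }
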