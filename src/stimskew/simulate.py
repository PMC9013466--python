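"""Negative-binomial count simulators with planted ground truth.

Two generative modes mirror the two study designs the pipeline targets:

* a single three-group study (control + two stimuli) with genes planted
  as core (regulated by both stimuli), stimulus-skewed (one stimulus, or
  used for discordant designs) or null;
* multiple case/control studies over a shared gene universe with planted
  co-regulation clusters (genes sharing a log2 fold-change vector across
  comparisons) and per-study batch effects.

Counts are NB with variance mu + phi*mu^2; the mean of gene g in sample s
is ``library_size_s * p_g * 2**log2fc`` where p_g are baseline proportions
drawn log-normally and normalized to sum to 1, and the fold-change applies
to case groups only.  Batch offsets are per-study-per-gene additive shifts
on the natural-log mean, shared by every sample of the study so that
within-study contrasts stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "SimulationConfig",
    "MetaSimulationConfig",
    "CATEGORIES",
    "simulate_three_group",
    "simulate_multistudy",
]

#: planted three-group categories, in planting order
CATEGORIES = (
    "core_up",
    "core_down",
    "stim1_up",
    "stim1_down",
    "stim2_up",
    "stim2_down",
)


def _default_fractions() -> dict:
    return {c: 0.03 for c in CATEGORIES}


@dataclass
class SimulationConfig:
    """Study conditions for the three-group simulator.

    ``baseline_logmean_mu/sd`` parameterize the natural-log of per-gene
    mean CPM before normalization to proportions; ``dispersion`` is the NB
    phi (variance = mu + phi*mu^2); ``library_sizes`` is a (min, max)
    range sampled uniformly per sample, or an explicit per-sample list;
    ``category_fractions`` gives the proportion of genes planted per
    category (remainder null) and ``effect_log2fc`` the planted |log2FC|.
    """

    n_genes: int = 2000
    groups: tuple = (("control", 5), ("stim1", 5), ("stim2", 5))
    baseline_logmean_mu: float = 3.0
    baseline_logmean_sd: float = 1.5
    dispersion: float = 0.1
    library_sizes: tuple = (800_000, 1_200_000)
    category_fractions: dict = field(default_factory=_default_fractions)
    effect_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name, n in self.groups:
            if n < 1:
                raise ValueError(f"group {name!r} has a non-positive replicate count")
        unknown = set(self.category_fractions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if any(f < 0 for f in self.category_fractions.values()):
            raise ValueError("category fractions must be >= 0")
        if sum(self.category_fractions.values()) > 1 + 1e-12:
            raise ValueError("category fractions sum to > 1")


def _library_sizes(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if len(spec) == 2 and np.isscalar(spec[0]) and n != 2:
        return rng.uniform(spec[0], spec[1], size=n)
    arr = np.asarray(spec, dtype=float)
    if arr.size == 2 and n == 2:
        # ambiguous: a 2-sample design with a (min, max) range
        return rng.uniform(arr[0], arr[1], size=2)
    if arr.size != n:
        raise ValueError("library_sizes must be a (min, max) range or one value per sample")
    if (arr <= 0).any():
        raise ValueError("library sizes must be positive")
    return arr


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.clip(mean, 1e-12, None)
    if phi <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    # NB as Gamma-Poisson mixture keeps vectorization simple
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_three_group(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a single three-group study with planted categories.

    Returns ``(CountMatrix, truth)`` where ``truth`` is indexed by gene id
    with columns ``category`` (one of CATEGORIES or ``"null"``),
    ``log2fc_stim1`` / ``log2fc_stim2`` / ``log2fc_stim1_vs_stim2`` (true
    contrast effects) and ``cluster`` (always NA here).  The same config
    and seed reproduce the output bitwise.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(G)], name="gene_id")

    base = np.exp(rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, G))
    props = base / base.sum()

    # plant categories on a random gene subset
    cats = np.array(["null"] * G, dtype=object)
    perm = rng.permutation(G)
    pos = 0
    for cat in CATEGORIES:
        n_cat = int(round(config.category_fractions.get(cat, 0.0) * G))
        cats[perm[pos : pos + n_cat]] = cat
        pos += n_cat

    e = config.effect_log2fc
    fc1 = np.zeros(G)  # true log2FC of stim1 vs control
    fc2 = np.zeros(G)
    fc1[cats == "core_up"] = e
    fc2[cats == "core_up"] = e
    fc1[cats == "core_down"] = -e
    fc2[cats == "core_down"] = -e
    fc1[cats == "stim1_up"] = e
    fc1[cats == "stim1_down"] = -e
    fc2[cats == "stim2_up"] = e
    fc2[cats == "stim2_down"] = -e

    sample_ids, group_of = [], []
    for name, n in config.groups:
        for r in range(n):
            sample_ids.append(f"{name}_{r+1}")
            group_of.append(name)
    libs = _library_sizes(config.library_sizes, len(sample_ids), rng)

    group_names = [name for name, _ in config.groups]
    control, stim1, stim2 = group_names[0], group_names[1], group_names[2]
    fc_of_group = {control: np.zeros(G), stim1: fc1, stim2: fc2}

    counts = np.empty((G, len(sample_ids)), dtype=np.int64)
    for j, (sid, grp) in enumerate(zip(sample_ids, group_of)):
        mean = libs[j] * props * 2.0 ** fc_of_group[grp]
        counts[:, j] = _nb_draw(rng, mean, config.dispersion)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        pd.DataFrame({"group": group_of, "study": "sim"}, index=pd.Index(sample_ids)),
    )
    truth = pd.DataFrame(
        {
            "category": cats,
            "log2fc_stim1": fc1,
            "log2fc_stim2": fc2,
            "log2fc_stim1_vs_stim2": fc1 - fc2,
            "cluster": pd.array([pd.NA] * G, dtype="Int64"),
        },
        index=gene_ids,
    )
    return cm, truth


@dataclass
class MetaSimulationConfig:
    """Study conditions for the multi-study simulator.

    ``studies`` lists (name, [(case, control), ...], n_replicates) — every
    group named in a comparison receives ``n_replicates`` samples.
    ``cluster_defs`` lists (cluster_id, n_genes, log2fc_by_comparison)
    where the fold-change mapping has one entry per (study, case, control)
    comparison (missing entries default to 0).  ``study_batch_sd`` is the
    standard deviation of per-study-per-gene additive offsets on the
    natural-log mean, applied to all samples of a study equally.
    """

    studies: list = field(
        default_factory=lambda: [
            ("studyA", [("case", "control")], 5),
            ("studyB", [("case", "control")], 5),
        ]
    )
    cluster_defs: list = field(default_factory=list)
    n_genes: int = 2000
    baseline_logmean_mu: float = 3.0
    baseline_logmean_sd: float = 1.5
    dispersion: float = 0.1
    library_sizes: tuple = (800_000, 1_200_000)
    study_batch_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [s[0] for s in self.studies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate study names")
        if len(self.studies) < 2:
            raise ValueError("need at least 2 studies")
        comps = self.comparison_names
        for cid, n, fcs in self.cluster_defs:
            if n < 1:
                raise ValueError(f"cluster {cid!r} has fewer than 1 gene")
            unknown = set(fcs) - set(comps)
            if unknown:
                raise ValueError(
                    f"cluster {cid!r} references undefined comparisons: {sorted(unknown)}"
                )
        total = sum(n for _, n, _ in self.cluster_defs)
        if total > self.n_genes:
            raise ValueError("cluster genes exceed n_genes")

    @property
    def comparison_names(self) -> list:
        return [
            f"{name}:{case}_vs_{control}"
            for name, comps, _ in self.studies
            for case, control in comps
        ]


def simulate_multistudy(config: MetaSimulationConfig) -> tuple[list, pd.DataFrame]:
    """Simulate one count matrix per study with planted clusters.

    Returns ``(studies, truth)``: ``studies`` is a list of
    ``(name, CountMatrix, comparisons)`` tuples over a shared gene
    universe, and ``truth`` holds each gene's cluster id (NA for null
    genes) and its true log2FC per comparison column.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(G)], name="gene_id")
    comps = config.comparison_names

    base = np.exp(rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, G))
    props = base / base.sum()

    cluster = pd.array([pd.NA] * G, dtype="Int64")
    fc = pd.DataFrame(0.0, index=gene_ids, columns=comps)
    perm = rng.permutation(G)
    pos = 0
    for cid, n, fcs in config.cluster_defs:
        idx = perm[pos : pos + n]
        cluster[idx] = cid
        for comp, value in fcs.items():
            fc.iloc[idx, fc.columns.get_loc(comp)] = value
        pos += n

    out = []
    for name, comparisons, n_rep in config.studies:
        batch = rng.normal(0.0, config.study_batch_sd, G)  # per-gene, whole study
        groups = []
        for case, control in comparisons:
            for g in (control, case):
                if g not in groups:
                    groups.append(g)
        sample_ids, group_of = [], []
        for g in groups:
            for r in range(n_rep):
                sample_ids.append(f"{name}_{g}_{r+1}")
                group_of.append(g)
        libs = _library_sizes(config.library_sizes, len(sample_ids), rng)

        # per-group true log2FC vector: a case group takes its comparison's
        # fold-changes; control groups sit at baseline
        group_fc = {g: np.zeros(G) for g in groups}
        for case, control in comparisons:
            comp = f"{name}:{case}_vs_{control}"
            group_fc[case] = group_fc[case] + fc[comp].to_numpy()

        counts = np.empty((G, len(sample_ids)), dtype=np.int64)
        for j, grp in enumerate(group_of):
            mean = libs[j] * props * np.exp(batch) * 2.0 ** group_fc[grp]
            counts[:, j] = _nb_draw(rng, mean, config.dispersion)
        cm = CountMatrix(
            pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
            pd.DataFrame({"group": group_of, "study": name}, index=pd.Index(sample_ids)),
        )
        out.append((name, cm, list(comparisons)))

    truth = pd.concat(
        [pd.DataFrame({"cluster": cluster}, index=gene_ids), fc.add_prefix("log2fc_")],
        axis=1,
    )
    return out, truth
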