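"""Cross-study Z-scoring, clustering and cluster summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

import stimskew as sk
from conftest import make_count_matrix


class TestZScoreWithinStudy:
    def test_hand_worked_standardization(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=["a", "b", "c"])
        z = sk.zscore_within_study(expr, ["S1", "S1", "S1"])
        assert np.allclose(z.loc["g0"], [-1, 0, 1])  # sample sd (ddof=1) = 1

    def test_constant_gene_maps_to_zeros(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g0"], columns=list("abc"))
        z = sk.zscore_within_study(expr, ["S1"] * 3)
        assert (z.loc["g0"] == 0).all()

    def test_per_study_offsets_removed_exactly(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(50, 8)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(8)],
        )
        studies = ["A"] * 4 + ["B"] * 4
        z0 = sk.zscore_within_study(expr, studies)
        shifted = expr.copy()
        # arbitrary per-study, per-gene constant offsets (batch effects)
        shifted.iloc[:, :4] += rng.normal(0, 3, size=(50, 1))
        shifted.iloc[:, 4:] += rng.normal(0, 3, size=(50, 1))
        z1 = sk.zscore_within_study(shifted, studies)
        assert np.allclose(z0.to_numpy(), z1.to_numpy(), atol=1e-12)

    def test_single_sample_study_is_error(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            sk.zscore_within_study(expr, ["A", "B"])


def brute_force_complete_linkage(X, k):
    """Independent agglomeration oracle: merge the pair of clusters with
    the smallest maximum pairwise Euclidean distance until k remain."""
    clusters = [[i] for i in range(len(X))]
    while len(clusters) > k:
        best, pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(X[i] - X[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if d < best:
                best, pair = d, (a, b)
        a, b = pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(X), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def _same_partition(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


class TestClusterGenes:
    def test_duplicated_profiles_separate_perfectly(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.normal(size=6), rng.normal(size=6) + 10
        X = np.vstack([p1] * 10 + [p2] * 10)
        zm = pd.DataFrame(X, index=[f"g{i}" for i in range(20)])
        ct = sk.cluster_genes(zm, k=2)
        labels = ct.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_duplicated_rows_always_share_a_cluster(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 5))
        X[5] = X[2]  # duplicate profile
        zm = pd.DataFrame(X, index=[f"g{i}" for i in range(8)])
        for k in range(1, 8):
            ct = sk.cluster_genes(zm, k=k)
            assert ct.labels.iloc[5] == ct.labels.iloc[2]

    def test_matches_brute_force_agglomeration_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        zm = pd.DataFrame(X, index=[f"g{i}" for i in range(6)])
        for k in range(1, 7):
            ours = sk.cluster_genes(zm, k=k).labels.to_numpy()
            oracle = brute_force_complete_linkage(X, k)
            assert _same_partition(ours, oracle), f"k={k}"

    def test_k_bounds(self):
        zm = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="exceeds"):
            sk.cluster_genes(zm, k=4)
        with pytest.raises(ValueError, match="k must be"):
            sk.cluster_genes(zm, k=0)


class TestRecurrentGeneSelection:
    def _tables(self, sig_matrix):
        genes = [f"g{i}" for i in range(sig_matrix.shape[0])]
        return {
            ("S", f"c{j}", "ctrl"): pd.DataFrame(
                {"significant": sig_matrix[:, j]}, index=genes
            )
            for j in range(sig_matrix.shape[1])
        }

    def test_boundary_inclusion_and_exclusion(self):
        sig = np.zeros((2, 6), dtype=bool)
        sig[0, :4] = True  # exactly 4 of 6
        sig[1, :3] = True  # 3 of 6
        tables = self._tables(sig)
        assert sk.select_recurrent_genes(tables, min_comparisons=4) == ["g0"]

    def test_toy_table_hand_count(self):
        rng = np.random.default_rng(4)
        sig = rng.random((12, 6)) < 0.5
        tables = self._tables(sig)
        got = sk.select_recurrent_genes(tables, min_comparisons=4)
        expected = [f"g{i}" for i in range(12) if sig[i].sum() >= 4]
        assert got == expected

    def test_monotone_in_min_comparisons(self):
        rng = np.random.default_rng(5)
        sig = rng.random((30, 6)) < 0.6
        tables = self._tables(sig)
        prev = None
        for k in range(1, 7):
            cur = set(sk.select_recurrent_genes(tables, min_comparisons=k))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_min_comparisons_bound(self):
        tables = self._tables(np.ones((2, 3), dtype=bool))
        with pytest.raises(ValueError):
            sk.select_recurrent_genes(tables, min_comparisons=4)


class TestClusterMedianFC:
    def _study_set(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(100, size=(6, 6))
        cm = make_count_matrix(counts, ["case"] * 3 + ["control"] * 3, study="S")
        return sk.StudySet([sk.Study("S", cm, [("case", "control")])])

    def test_median_interpolation(self):
        ss = self._study_set()
        ct = sk.ClusterTable(pd.Series([1, 1, 1, 2, 2, 3],
                                       index=[f"g{i}" for i in range(6)]))
        med, gene_fc = sk.cluster_median_fc(ss, ct)
        col = gene_fc.columns[0]
        # odd cluster -> middle value; even cluster -> midpoint
        assert med.loc[1, col] == pytest.approx(np.median(gene_fc[col].iloc[:3]))
        assert med.loc[2, col] == pytest.approx(gene_fc[col].iloc[3:5].mean())

    def test_all_zero_means_give_zero_median(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[2] = [50, 60, 55, 45]  # keeps library sizes positive
        cm = make_count_matrix(counts, ["case", "case", "control", "control"], study="S")
        ss = sk.StudySet([sk.Study("S", cm, [("case", "control")])])
        ct = sk.ClusterTable(pd.Series([1, 1], index=["g0", "g1"]))
        med, _ = sk.cluster_median_fc(ss, ct)
        assert med.iloc[0, 0] == pytest.approx(0.0)

    def test_missing_cluster_gene_is_error(self):
        ss = self._study_set()
        ct = sk.ClusterTable(pd.Series([1], index=["not_a_gene"]))
        with pytest.raises(ValueError, match="lacks"):
            sk.cluster_median_fc(ss, ct)


class TestSetOverlapShare:
    def test_containment_disjoint_and_hand_value(self):
        assert sk.set_overlap_share({"a", "b"}, {"a", "b", "c"}) == 100.0
        assert sk.set_overlap_share({"a"}, {"b"}) == 0.0
        cluster = {f"g{i}" for i in range(40)}
        reference = {f"g{i}" for i in range(13)} | {"x", "y"}
        assert sk.set_overlap_share(cluster, reference) == 32.5
        with pytest.raises(ValueError):
            sk.set_overlap_share(set(), {"a"})


class TestStudySetAndPerStudyDEG:
    def test_gene_universe_intersection_with_warning(self):
        rng = np.random.default_rng(7)
        cm1 = make_count_matrix(rng.poisson(50, (5, 4)),
                                ["case"] * 2 + ["control"] * 2, study="A")
        cm2 = make_count_matrix(rng.poisson(50, (4, 4)),
                                ["case"] * 2 + ["control"] * 2, study="B")
        with pytest.warns(UserWarning, match="intersecting"):
            ss = sk.StudySet([sk.Study("A", cm1, [("case", "control")]),
                              sk.Study("B", cm2, [("case", "control")])])
        assert all(s.counts.n_genes == 4 for s in ss.studies)

    def test_undefined_comparison_group_rejected(self):
        cm = make_count_matrix(np.ones((3, 4), dtype=int) * 5,
                               ["case"] * 2 + ["control"] * 2)
        with pytest.raises(ValueError, match="undefined group"):
            sk.Study("A", cm, [("case", "nope")])

    def test_planted_effect_detected_only_in_its_study(self):
        comps = ["A:case_vs_control", "B:case_vs_control"]
        cfg = sk.MetaSimulationConfig(
            seed=10, n_genes=800, study_batch_sd=0.5,
            studies=[("A", [("case", "control")], 5), ("B", [("case", "control")], 5)],
            cluster_defs=[(1, 30, {comps[0]: 2.5})],  # study A only
        )
        studies, truth = sk.simulate_multistudy(cfg)
        ss = sk.StudySet([sk.Study(n, c, cp) for n, c, cp in studies])
        degs = sk.per_study_deg(ss)
        planted = truth.index[truth["cluster"].notna()]
        degA = degs[("A", "case", "control")]
        degB = degs[("B", "case", "control")]
        inA = planted.intersection(degA.index)
        inB = planted.intersection(degB.index)
        assert degA.loc[inA, "significant"].mean() >= 0.8
        assert degB.loc[inB, "significant"].mean() <= 0.1
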