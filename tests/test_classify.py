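"""Two-way core / skewed classification."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import stimskew as sk
from stimskew.classify import CORE, NOT_REGULATED, STIM1_SKEWED, STIM2_SKEWED


def oracle_classify(sig1, dir1, sig2, dir2, sig12, absfc1, absfc2):
    """Brute-force restatement of the published category definitions.

    Core: DE in both vs-control contrasts (same direction) with no
    significant between-stimulus difference.  Stimulus-1-skewed: DE only
    under stimulus 1; or DE in both plus between the stimuli (assigned to
    the stimulus with the larger response); or up under 1 while down
    under 2.  Stimulus-2-skewed: symmetric.  Everything else unregulated.
    """
    if sig1 and sig2:
        if dir1 > 0 and dir2 < 0:
            return STIM1_SKEWED
        if dir2 > 0 and dir1 < 0:
            return STIM2_SKEWED
        if sig12:
            if absfc1 > absfc2:
                return STIM1_SKEWED
            if absfc2 > absfc1:
                return STIM2_SKEWED
            return CORE  # documented fallback for an exact tie
        return CORE
    if sig1:
        return STIM1_SKEWED
    if sig2:
        return STIM2_SKEWED
    return NOT_REGULATED


class TestPseudoFC:
    @pytest.mark.parametrize(
        "case, control, expected",
        [(10, 10, 0.0), (0, 0, 0.0), (8, 0, np.log2(65))],
    )
    def test_hand_arithmetic(self, case, control, expected):
        assert sk.pseudo_fc(case, control) == pytest.approx(expected)

    def test_rejects_negative_means_and_pseudo(self):
        with pytest.raises(ValueError):
            sk.pseudo_fc(-1, 2)
        with pytest.raises(ValueError):
            sk.pseudo_fc(1, 2, pseudo=0)

    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=1e6),
    )
    def test_always_finite_and_antisymmetric(self, a, b):
        fc = sk.pseudo_fc(a, b)
        assert np.isfinite(fc)
        assert fc == pytest.approx(-sk.pseudo_fc(b, a))


class TestClassifyGene:
    def test_exhaustive_truth_table_matches_oracle(self):
        """classify_gene agrees with the textual-rule oracle everywhere."""
        magnitudes = [(0.4, 2.2), (2.2, 0.4), (1.3, 1.3)]
        n_checked = 0
        for sig1, sig2, sig12 in itertools.product([False, True], repeat=3):
            for dir1, dir2 in itertools.product([-1, 1], repeat=2):
                for absfc1, absfc2 in magnitudes:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        got = sk.classify_gene(
                            sig1, dir1, sig2, dir2, sig12, absfc1, absfc2
                        )
                    want = oracle_classify(
                        sig1, dir1, sig2, dir2, sig12, absfc1, absfc2
                    )
                    assert got == want, (sig1, dir1, sig2, dir2, sig12, absfc1, absfc2)
                    n_checked += 1
        assert n_checked == 96

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((False, 0, False, 0, False, 0, 0), NOT_REGULATED),
            ((True, 1, False, 0, False, 2, 0), STIM1_SKEWED),
            ((True, 1, True, 1, False, 2, 2), CORE),
            ((True, -1, True, 1, False, 2, 2), STIM2_SKEWED),  # discordant
        ],
    )
    def test_published_rule_examples(self, args, expected):
        assert sk.classify_gene(*args) == expected

    def test_exact_tie_warns_and_returns_core(self):
        with pytest.warns(UserWarning, match="tied"):
            assert sk.classify_gene(True, 1, True, 1, True, 1.5, 1.5) == CORE

    def test_symmetry_under_stimulus_relabeling(self):
        """Swapping stimulus roles swaps the skew labels, fixes CORE."""
        swap = {STIM1_SKEWED: STIM2_SKEWED, STIM2_SKEWED: STIM1_SKEWED,
                CORE: CORE, NOT_REGULATED: NOT_REGULATED}
        magnitudes = [(0.4, 2.2), (2.2, 0.4)]
        for sig1, sig2, sig12 in itertools.product([False, True], repeat=3):
            for dir1, dir2 in itertools.product([-1, 1], repeat=2):
                for a1, a2 in magnitudes:
                    fwd = sk.classify_gene(sig1, dir1, sig2, dir2, sig12, a1, a2)
                    rev = sk.classify_gene(sig2, dir2, sig1, dir1, sig12, a2, a1)
                    assert rev == swap[fwd]

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            sk.classify_gene(True, 0, False, 0, False, 1, 1)
        with pytest.raises(ValueError):
            sk.classify_gene(True, 1, True, 1, False, -1, 1)


def _triplet(sig1, fc1, sig2, fc2, sig12):
    """Build a ContrastTriplet whose pseudocount FCs equal fc1/fc2."""
    n = len(sig1)
    idx = pd.Index([f"g{i}" for i in range(n)])

    def deg(sig):
        return pd.DataFrame(
            {"log2fc": 0.0, "pvalue": 0.5, "fdr": 0.5,
             "mean_expr": 1.0, "significant": sig},
            index=idx,
        )

    pseudo = 0.125
    control = np.full(n, 10.0)
    means = pd.DataFrame(
        {
            "control": control,
            "stim1": (control + pseudo) * 2.0 ** np.asarray(fc1, dtype=float) - pseudo,
            "stim2": (control + pseudo) * 2.0 ** np.asarray(fc2, dtype=float) - pseudo,
        },
        index=idx,
    )
    return sk.ContrastTriplet(
        deg(sig1), deg(sig2), deg(sig12), means,
        control="control", stim1="stim1", stim2="stim2",
    )


class TestTwowayUniverseAndClassifyAll:
    def test_universe_union_rule_on_toy_genes(self):
        # 8 genes with mixed flags; hand evaluation of the union rule
        sig1 = [True, True, False, False, True, False, True, False]
        fc1 = [1.5, 0.5, 2.0, 0.0, -1.2, 0.4, 1.0, 3.0]
        sig2 = [False, True, True, False, False, True, False, False]
        fc2 = [0.0, 0.5, 1.1, 0.0, 0.3, -2.5, 0.9, 0.1]
        trip = _triplet(sig1, fc1, sig2, fc2, [False] * 8)
        got = set(sk.twoway_universe(trip, min_abs_log2fc=1.0))
        # g0: sig1 & |1.5|>=1 -> in; g1: both sig but |fc|<1 -> out;
        # g2: sig2 & 1.1 -> in; g3: nothing -> out; g4: sig1 & |-1.2| -> in;
        # g5: sig2 & |-2.5| -> in; g6: sig1 but |1.0|>=1 -> in; g7: not sig -> out
        assert got == {"g0", "g2", "g4", "g5", "g6"}

    def test_classify_all_partition_and_restriction(self):
        sig1 = [True, True, False, True]
        fc1 = [2.0, 0.5, 0.0, 1.5]
        sig2 = [True, True, False, False]
        fc2 = [2.0, 0.5, 0.0, 0.0]
        trip = _triplet(sig1, fc1, sig2, fc2, [False] * 4)
        table = sk.classify_all(trip, restrict_to_universe=True)
        assert table.loc["g0", "category"] == CORE
        # g1 significant both but below twofold -> outside the universe
        assert table.loc["g1", "category"] == NOT_REGULATED
        assert table.loc["g2", "category"] == NOT_REGULATED
        assert table.loc["g3", "category"] == STIM1_SKEWED
        # every gene receives exactly one category
        assert table["category"].isin(
            [CORE, STIM1_SKEWED, STIM2_SKEWED, NOT_REGULATED]
        ).all()
        unrestricted = sk.classify_all(trip, restrict_to_universe=False)
        assert unrestricted.loc["g1", "category"] == CORE

    def test_empty_significant_sets(self):
        trip = _triplet([False] * 3, [2.0, 0.0, -2.0], [False] * 3,
                        [0.0, 1.0, 0.0], [False] * 3)
        table = sk.classify_all(trip)
        assert (table["category"] == NOT_REGULATED).all()
        assert (table["direction"] == 0).all()


class TestCategoryShare:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((144, 143, 675, 435), 20.5),
            ((144, 143, 252, 237), 37.0),
            ((0, 0, 10, 0), 0.0),
        ],
    )
    def test_share_arithmetic(self, counts, expected):
        assert sk.category_share(*counts) == expected

    def test_all_zero_denominator(self):
        with pytest.raises(ValueError):
            sk.category_share(0, 0, 0, 0)
        with pytest.raises(ValueError):
            sk.category_share(-1, 0, 1, 0)


class TestTwoWaySkewClassifierEstimator:
    def test_fit_recovers_planted_categories(self, planted_three_group):
        cm, truth = planted_three_group
        cm = sk.filter_low_counts(cm)
        est = sk.TwoWaySkewClassifier(control="control", stim1="stim1", stim2="stim2")
        est.fit(cm.counts.to_numpy().T, cm.groups.to_numpy())
        table = est.categories_
        table.index = cm.gene_ids
        tr = truth.loc[cm.gene_ids]
        core = tr["category"].isin(["core_up", "core_down"])
        assert (table.loc[core, "category"] == CORE).mean() >= 0.7
        assert est.summary_["CORE_up"] > 0
        # sklearn parameter protocol
        assert est.get_params()["alpha"] == 0.05
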