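"""SVM classification: weight-ranked selection arithmetic, LOOCV
honesty, permutation p-values, Bonferroni flags, cross-site protocol
and ROC/AUC."""

import itertools

import numpy as np
import pytest

from csmfc.classify import (
    DEFAULT_FRACTIONS,
    PermutationNull,
    bonferroni_adjust,
    cross_site_classify,
    loocv_classify,
    permutation_test_accuracy,
    roc_auc,
    select_top_features,
)


def auc_pair_oracle(scores, labels):
    """Mann-Whitney pair counting: P(score_pos > score_neg) + ties/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_separable(rng, n_per_class=8, n_feat=30, gap=4.0):
    x = rng.standard_normal((2 * n_per_class, n_feat))
    y = np.repeat([0, 1], n_per_class)
    x[y == 1, :3] += gap
    return x, y


class TestSelectTopFeatures:
    @pytest.mark.parametrize(
        "fraction, expected_k",
        [(0.15, 1001), (0.25, 1668), (0.30, 2001), (0.05, 334), (1.0, 6670)],
    )
    def test_round_half_up_on_6670_edges(self, fraction, expected_k, rng):
        w = rng.standard_normal(6670)
        assert len(select_top_features(w, fraction)) == expected_k

    def test_selects_largest_absolute_weights(self):
        w = np.array([0.1, -5.0, 0.2, 4.0, -0.3])
        np.testing.assert_array_equal(select_top_features(w, 0.4), [1, 3])

    def test_tie_break_by_ascending_index(self):
        w = np.ones(4)
        np.testing.assert_array_equal(select_top_features(w, 0.5), [0, 1])

    def test_zero_selection_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            select_top_features(np.ones(4), 0.01)

    def test_nonfinite_weights_rejected(self):
        with pytest.raises(ValueError):
            select_top_features(np.array([1.0, np.nan]), 0.5)


class TestLoocvClassify:
    def test_separable_classes_perfect_at_every_fraction(self, rng):
        x, y = make_separable(rng)
        run = loocv_classify(x, y, fractions=(0.1, 0.5, 1.0))
        np.testing.assert_array_equal(run.accuracies, [1.0, 1.0, 1.0])
        assert run.n_folds == len(y)

    def test_fraction_one_equals_no_selection(self, rng):
        """The fraction-1.0 column must reproduce the plain no-selection
        LOOCV bitwise (it is the same classifier)."""
        x = rng.standard_normal((14, 25))
        y = np.repeat([0, 1], 7)
        x[y == 1, 0] += 1.0
        run = loocv_classify(x, y, fractions=(1.0,))
        # manual no-selection LOOCV
        from sklearn.svm import SVC

        for hold in range(14):
            mask = np.ones(14, bool)
            mask[hold] = False
            clf = SVC(kernel="linear", C=1.0).fit(x[mask], y[mask])
            assert run.predictions[0, hold] == clf.predict(x[hold : hold + 1])[0]
            assert run.decision_values[0, hold] == pytest.approx(
                float(clf.decision_function(x[hold : hold + 1])[0])
            )

    def test_duplicating_features_keeps_full_predictions(self, rng):
        x = rng.standard_normal((12, 10))
        y = np.repeat([0, 1], 6)
        x[y == 1, 0] += 1.5
        a = loocv_classify(x, y, fractions=(1.0,))
        b = loocv_classify(np.hstack([x, x]), y, fractions=(1.0,))
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_subject_order_invariance(self, rng):
        x = rng.standard_normal((14, 20))
        y = np.repeat([0, 1], 7)
        x[y == 1, :2] += 1.0
        perm = rng.permutation(14)
        a = loocv_classify(x, y, fractions=(0.2, 1.0))
        b = loocv_classify(x[perm], y[perm], fractions=(0.2, 1.0))
        np.testing.assert_allclose(a.accuracies, b.accuracies)

    def test_underpopulated_class_rejected(self, rng):
        x = rng.standard_normal((5, 4))
        # a singleton class would leave some training fold one-class
        with pytest.raises(ValueError, match="class"):
            loocv_classify(x, np.array([0, 0, 0, 0, 1]), fractions=(1.0,))
        # 2 per class minimum: removing one leaves the class represented
        loocv_classify(
            np.vstack([x, x[:1]]), np.array([0, 0, 0, 1, 1, 1]), fractions=(1.0,)
        )

    def test_selection_can_match_or_beat_no_selection_on_strong_signal(self):
        """At a fixed strong-signal cohort and seed, at least one reduced
        fraction performs no worse than the full-feature analysis (the
        benefit is not guaranteed in theory; this pins one regime where
        discarding noise edges pays off)."""
        from csmfc import synth
        from csmfc.features import feature_table

        cfg = synth.SyntheticConfig(
            n_rois=10,
            sites=(synth.SiteConfig(15, 15, 60, 2.0),),
            n_disc_edges=5,
            disc_effect=0.25,
            n_score_edges=0,
            seed=13,
        )
        co = synth.generate_cohort(cfg)
        df = feature_table(co.series, [s.subject_id for s in co.subjects], clean=False)
        x = df.drop(columns="subject_id").to_numpy()
        y = np.array([s.group == "patient" for s in co.subjects])
        run = loocv_classify(x, y, fractions=(0.1, 0.25, 0.5, 1.0))
        assert run.accuracies[:-1].max() >= run.accuracies[-1]
        assert run.accuracies[-1] > 0.8  # the signal really is strong

    def test_grid_validation(self, rng):
        x, y = make_separable(rng, 4, 10)
        with pytest.raises(ValueError, match="increasing"):
            loocv_classify(x, y, fractions=(0.5, 0.2))
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            loocv_classify(x, y, fractions=(0.0, 0.5))


class TestPermutationTest:
    def test_trivial_tails(self):
        low = PermutationNull(observed=0.2, null=np.linspace(0.4, 0.9, 10))
        assert low.p == 1.0 and not low.floored
        high = PermutationNull(observed=0.95, null=np.linspace(0.4, 0.9, 1000))
        assert high.floored and high.p_label == "< 0.001"

    def test_separable_data_significant(self, rng):
        x, y = make_separable(rng, 6, 15)
        _, tests = permutation_test_accuracy(x, y, fractions=(1.0,), n_perm=49, seed=1)
        assert tests[0].p < 0.05

    def test_perm_fixed_features_inflates_significance(self, rng):
        """Reusing the originally selected feature sets in permutations is
        anti-conservative: its null accuracies sit at or below the honest
        rerun's null on average."""
        x = rng.standard_normal((16, 60))
        y = np.repeat([0, 1], 8)
        x[y == 1, :3] += 1.0
        _, honest = permutation_test_accuracy(
            x, y, fractions=(0.1,), n_perm=30, seed=3
        )
        _, fixed = permutation_test_accuracy(
            x, y, fractions=(0.1,), n_perm=30, seed=3, perm_fixed_features=True
        )
        assert fixed[0].null.mean() <= honest[0].null.mean() + 0.05


class TestBonferroni:
    def test_threshold_for_twenty_fractions(self):
        p = np.full(20, 0.01)
        p[3] = 0.002
        flags = bonferroni_adjust(p, 0.05)
        assert flags[3] and flags.sum() == 1  # threshold 0.05/20 = 0.0025

    def test_boundary_is_strict(self):
        assert not bonferroni_adjust(np.full(20, 0.0025), 0.05).any()

    def test_single_test_reduces_to_alpha(self):
        assert bonferroni_adjust(np.array([0.04]), 0.05)[0]


class TestCrossSite:
    def test_identical_separable_sites_perfect(self, rng):
        x, y = make_separable(rng, 8, 20)
        res = cross_site_classify(x, y, x.copy(), y.copy(), fractions=(0.25, 1.0))
        np.testing.assert_array_equal(res.mean_accuracies, [1.0, 1.0])
        assert res.roc["a_to_b"].auc == 1.0

    def test_flipped_test_site_below_chance(self, rng):
        """A test site whose class-conditional means are swapped must score
        below chance: the metric is direction sensitive."""
        xa, ya = make_separable(rng, 10, 15, gap=3.0)
        xb = xa.copy()
        yb = 1 - ya  # same clusters, opposite labels
        res = cross_site_classify(xa, ya, xb, yb, fractions=(1.0,))
        assert res.accuracies["a_to_b"][0] < 0.2

    def test_mismatched_edges_rejected(self, rng):
        xa, ya = make_separable(rng, 4, 10)
        xb, yb = make_separable(rng, 4, 11)
        with pytest.raises(ValueError, match="mismatch"):
            cross_site_classify(xa, ya, xb, yb)

    def test_mean_is_average_of_directions(self, rng):
        xa, ya = make_separable(rng, 6, 12, gap=1.0)
        xb, yb = make_separable(rng, 7, 12, gap=1.0)
        res = cross_site_classify(xa, ya, xb, yb, fractions=(0.5, 1.0))
        np.testing.assert_allclose(
            res.mean_accuracies,
            (res.accuracies["a_to_b"] + res.accuracies["b_to_a"]) / 2,
        )


class TestRocAuc:
    def test_perfect_ranking(self):
        res = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        res = roc_auc(np.zeros(8), np.repeat([0, 1], 4))
        assert res.auc == pytest.approx(0.5)

    def test_six_point_hand_example(self):
        scores = np.array([0.9, 0.4, 0.65, 0.35, 0.8, 0.5])
        labels = np.array([1, 0, 1, 0, 0, 1])
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(auc_pair_oracle(scores, labels))

    def test_matches_pair_oracle_exhaustively(self, rng):
        """All class splits at n <= 9 plus random draws up to n = 12."""
        for n in range(4, 10):
            scores = rng.standard_normal(n)
            for labels in itertools.product([0, 1], repeat=n):
                y = np.array(labels)
                if y.sum() in (0, n):
                    continue
                assert roc_auc(scores, y).auc == pytest.approx(
                    auc_pair_oracle(scores, y)
                )
        for n in (10, 11, 12):
            for _ in range(30):
                scores = np.round(rng.standard_normal(n), 1)  # force ties
                y = rng.integers(0, 2, n)
                if y.sum() in (0, n):
                    continue
                assert roc_auc(scores, y).auc == pytest.approx(
                    auc_pair_oracle(scores, y)
                )

    def test_curve_endpoints(self, rng):
        res = roc_auc(rng.standard_normal(20), rng.permutation(np.repeat([0, 1], 10)))
        assert res.sensitivities[0] == 0.0 and res.sensitivities[-1] == 1.0
        assert res.specificities[0] == 1.0 and res.specificities[-1] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))
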