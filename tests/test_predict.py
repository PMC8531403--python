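"""SVR prediction: per-fold correlation filtering, LOOCV honesty,
metrics, permutation tails and the cross-site protocol."""

import numpy as np
import pytest
from scipy import stats

from csmfc.predict import (
    correlation_feature_filter,
    cross_site_regress,
    evaluate_prediction,
    loocv_regress,
    permutation_test_regression,
)


def make_linear(rng, n=30, n_signal=3, n_noise=40, noise_sd=0.05):
    x = rng.standard_normal((n, n_signal + n_noise))
    beta = np.array([1.0, -0.8, 0.6])
    y = x[:, :n_signal] @ beta + noise_sd * rng.standard_normal(n)
    return x, y


class TestCorrelationFilter:
    def test_label_copy_is_kept(self, rng):
        x = rng.standard_normal((20, 5))
        y = x[:, 2].copy()
        idx = correlation_feature_filter(x, y, 0.05)
        assert 2 in idx

    def test_p_matches_closed_form(self):
        """5-point hand example against t = r sqrt((n-2)/(1-r^2))."""
        x = np.array([[1.0], [2.0], [3.5], [4.0], [6.0]])
        y = np.array([1.2, 1.9, 3.1, 4.5, 5.5])
        r = stats.pearsonr(x[:, 0], y)
        t = r.statistic * np.sqrt(3 / (1 - r.statistic**2))
        p = 2 * stats.t.sf(abs(t), 3)
        kept_strict = correlation_feature_filter(x, y, min(p * 1.001, 0.999))
        kept_below = correlation_feature_filter(x, y, max(p * 0.999, 1e-12))
        assert 0 in kept_strict  # alpha just above p keeps it
        assert 0 not in kept_below  # strict <: alpha just below p drops it

    def test_null_keep_rate_near_alpha(self, rng):
        kept = 0
        total = 0
        for _ in range(40):
            x = rng.standard_normal((20, 50))
            y = rng.standard_normal(20)
            kept += len(correlation_feature_filter(x, y, 0.05))
            total += 50
        rate = kept / total
        assert 0.02 < rate < 0.09  # ~5% of pure-noise features pass

    def test_constant_label_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            correlation_feature_filter(rng.standard_normal((10, 3)), np.ones(10))

    def test_minimum_n(self, rng):
        with pytest.raises(ValueError, match=">= 4"):
            correlation_feature_filter(rng.standard_normal((3, 2)), np.arange(3.0))


class TestLoocvRegress:
    def test_strong_linear_signal_recovered(self, rng):
        x, y = make_linear(rng)
        run = loocv_regress(x, y)
        assert run.r > 0.95

    def test_null_r_centred_on_zero(self, rng):
        rs = []
        for _ in range(15):
            x = rng.standard_normal((20, 30))
            y = rng.standard_normal(20)
            rs.append(loocv_regress(x, y).r)
        assert abs(np.mean(rs)) < 0.25

    def test_no_leakage_metamorphic(self, rng):
        """Changing the held-out subject's label cannot change that
        subject's prediction."""
        x, y = make_linear(rng, n=15)
        run = loocv_regress(x, y)
        y2 = y.copy()
        y2[4] += 100.0
        run2 = loocv_regress(x, y2)
        assert run2.predicted[4] == pytest.approx(run.predicted[4])

    def test_filter_before_cv_leaks(self, rng):
        """The broken protocol (filter on all subjects, then LOOCV) shows
        optimistic r on permuted labels; the honest per-fold filter does
        not. This is the critical correctness property."""
        rs_honest, rs_broken = [], []
        for _ in range(15):
            x = rng.standard_normal((20, 200))
            y = rng.standard_normal(20)
            rs_honest.append(loocv_regress(x, y).r)
            rs_broken.append(loocv_regress(x, y, filter_before_cv=True).r)
        assert np.mean(rs_broken) > np.mean(rs_honest) + 0.3
        assert abs(np.mean(rs_honest)) < 0.25

    def test_empty_selection_falls_back_to_mean(self, rng):
        x = rng.standard_normal((8, 3)) * 1e-12  # nothing correlates
        y = np.arange(8.0)
        run = loocv_regress(x, y, alpha=1e-6)
        for hold in range(8):
            others = np.delete(y, hold)
            assert run.predicted[hold] == pytest.approx(others.mean())

    def test_minmax_scaling_bounds(self, rng):
        x, y = make_linear(rng, n=20)
        run = loocv_regress(x, y, label_scaling="minmax")
        assert run.label_scaling == "minmax"
        assert np.all(run.actual >= -0.5) and np.all(run.actual <= 1.5)
        assert run.rmse < 0.5  # scaled units

    def test_constant_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            loocv_regress(rng.standard_normal((8, 3)), np.ones(8))


class TestEvaluatePrediction:
    def test_identity(self):
        r, rmse = evaluate_prediction(np.arange(5.0), np.arange(5.0))
        assert r == pytest.approx(1.0) and rmse == 0.0

    def test_offset_blindness_of_r(self):
        r, rmse = evaluate_prediction(np.arange(5.0) + 2.0, np.arange(5.0))
        assert r == pytest.approx(1.0) and rmse == pytest.approx(2.0)

    def test_four_point_hand_example(self):
        p = np.array([1.0, 2.0, 2.5, 4.0])
        a = np.array([1.5, 1.5, 3.0, 3.5])
        r, rmse = evaluate_prediction(p, a)
        assert r == pytest.approx(stats.pearsonr(p, a).statistic)
        assert rmse == pytest.approx(np.sqrt(np.mean((p - a) ** 2)))

    def test_rmse_zero_iff_equal(self, rng):
        p = rng.standard_normal(6)
        assert evaluate_prediction(p, p)[1] == 0.0
        assert evaluate_prediction(p, p + 1e-3)[1] > 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_prediction(np.arange(4.0), np.arange(5.0))


class TestPermutationRegression:
    def test_tail_directions(self):
        from csmfc.classify import PermutationNull

        pr = PermutationNull(observed=-0.5, null=np.linspace(-0.2, 0.6, 9), tail="ge")
        assert pr.p == 1.0
        prmse = PermutationNull(observed=5.0, null=np.linspace(1.0, 2.0, 9), tail="le")
        assert prmse.p == 1.0

    def test_signal_beats_null(self, rng):
        x, y = make_linear(rng, n=20, n_noise=20)
        obs, pr, prmse = permutation_test_regression(x, y, n_perm=29, seed=5)
        assert pr.p < 0.1
        assert prmse.p < 0.1


class TestCrossSiteRegress:
    def test_identical_sites_strong_signal(self, rng):
        x, y = make_linear(rng, n=30)
        runs = cross_site_regress(x, y, x.copy(), y.copy())
        assert runs["a_to_b"].r > 0.9 and runs["b_to_a"].r > 0.9

    def test_unlinked_sites_near_zero(self, rng):
        xa, ya = rng.standard_normal((25, 30)), rng.standard_normal(25)
        xb, yb = rng.standard_normal((25, 30)), rng.standard_normal(25)
        runs = cross_site_regress(xa, ya, xb, yb)
        assert abs(runs["a_to_b"].r) < 0.55

    def test_label_shift_translation_property(self, rng):
        """Shifting test-site labels by a constant leaves r unchanged and
        pushes the RMSE up by about the shift."""
        x, y = make_linear(rng, n=30, noise_sd=0.02)
        base = cross_site_regress(x, y, x.copy(), y.copy())["a_to_b"]
        shifted = cross_site_regress(x, y, x.copy(), y + 3.0)["a_to_b"]
        assert shifted.r == pytest.approx(base.r, abs=1e-9)
        assert shifted.rmse == pytest.approx(3.0, abs=0.4)

    def test_edge_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross_site_regress(
                rng.standard_normal((10, 5)),
                rng.standard_normal(10),
                rng.standard_normal((10, 6)),
                rng.standard_normal(10),
            )
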