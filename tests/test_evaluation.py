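"""Metrics, ROC/AUC, DCA, cross-validation and statistical tests."""

import numpy as np
import pytest
from scipy import stats

from dermagents.errors import DomainError
from dermagents.evaluation import (
    ConfusionMatrix,
    confusion_metrics,
    dca_curve,
    net_benefit,
    one_way_anova,
    roc_auc,
    stratified_kfold,
    tukey_hsd,
)

# the published worked example: 155/160 benign and 35/40 malignant correct
WORKED_CM = ConfusionMatrix(tp=35, fn=5, fp=5, tn=155)


class TestConfusionMetrics:
    def test_worked_example_counts(self):
        m = confusion_metrics(WORKED_CM)
        assert m.recall == pytest.approx(0.875)
        assert m.accuracy == pytest.approx(0.95)
        assert m.precision == pytest.approx(0.875)
        assert m.specificity == pytest.approx(155 / 160)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=7, fn=0, fp=0, tn=13))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_metrics_are_nan_not_exceptions(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
        assert np.isnan(m.precision) and np.isnan(m.recall) and np.isnan(m.f1)
        assert m.accuracy == 1.0

    def test_f1_is_harmonic_mean(self):
        m = confusion_metrics(ConfusionMatrix(tp=30, fn=10, fp=20, tn=40))
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall)
        )

    def test_from_predictions(self):
        y_true = np.array([1] * 40 + [0] * 160)
        y_pred = np.array([1] * 35 + [0] * 5 + [1] * 5 + [0] * 155)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (35, 5, 5, 155)

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_small_example_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        # independent oracle: concordance over all positive/negative pairs
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(conc) == pytest.approx(0.75)

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        _, auc = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(2)
        pts, _ = roc_auc(rng.random(100), rng.integers(0, 2, 100))
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([0.1, 0.2], [1, 1])


class TestNetBenefit:
    def test_perfect_model_equals_prevalence(self):
        for thr in (0.01, 0.1, 0.29):
            assert net_benefit(1.0, 1.0, 0.2, thr) == pytest.approx(0.2)

    def test_worked_value_from_confusion_counts(self):
        # sens/spec from the worked-example counts at threshold 0.05
        nb = net_benefit(0.875, 0.96875, 0.2, 0.05)
        assert nb == pytest.approx(0.875 * 0.2 - (1 - 0.96875) * 0.8 * (0.05 / 0.95))
        assert nb == pytest.approx(0.17368421052631577)

    def test_treat_all_crosses_zero_at_prevalence(self):
        assert net_benefit(1.0, 0.0, 0.2, 0.2) == pytest.approx(0.0)

    def test_low_threshold_limit(self):
        assert net_benefit(0.9, 0.8, 0.2, 1e-9) == pytest.approx(0.9 * 0.2)

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(DomainError):
            net_benefit(0.9, 0.9, 0.2, 1.0)

    def test_curve_pointwise_matches_formula(self):
        curve = dca_curve(0.875, 0.96875, prevalence=0.2)
        assert np.all(curve.treat_none == 0.0)
        assert curve.thresholds.min() >= 0.01 and curve.thresholds.max() <= 0.3
        for thr, nb, ta in zip(curve.thresholds, curve.net_benefit, curve.treat_all):
            assert nb == pytest.approx(net_benefit(0.875, 0.96875, 0.2, thr))
            assert ta == pytest.approx(net_benefit(1.0, 0.0, 0.2, thr))


class TestStratifiedKFold:
    def test_exact_stratification_when_divisible(self):
        labels = np.array([1] * 40 + [0] * 160)
        folds = stratified_kfold(labels, 5, seed=0)
        for fold in folds:
            assert (labels[fold] == 1).sum() == 8
            assert (labels[fold] == 0).sum() == 32

    def test_partition_property(self):
        labels = np.array([0, 1] * 20)
        folds = stratified_kfold(labels, 4, seed=1)
        joined = np.concatenate(folds)
        assert sorted(joined) == list(range(40))

    def test_two_samples_per_class_k2(self):
        folds = stratified_kfold([0, 0, 1, 1], 2, seed=0)
        for fold in folds:
            assert len(fold) == 2

    def test_seed_reproducibility(self):
        labels = np.array([0, 1] * 30)
        a = stratified_kfold(labels, 3, seed=7)
        b = stratified_kfold(labels, 3, seed=7)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa, fb)

    def test_small_class_rejected(self):
        with pytest.raises(DomainError):
            stratified_kfold([0, 0, 0, 1], 2, seed=0)


class TestANOVA:
    def test_hand_computed_f(self):
        f, p = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)
        assert 0 < p < 1

    def test_identical_groups_give_zero_f(self):
        f, _ = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)

    def test_degenerate_variance_marker(self):
        f, p = one_way_anova([[1, 1, 1], [1, 1, 1]])
        assert np.isnan(f) and np.isnan(p)

    def test_null_calibration(self):
        """Type-I error of the F test at alpha=0.05 over 2000 null draws."""
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = rng.normal(size=(3, 10))
            _, p = one_way_anova(list(groups))
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.01


class TestTukey:
    def test_two_groups_match_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        tk = tukey_hsd([a, b])
        _, p_t = stats.ttest_ind(a, b)
        assert tk.loc[0, "p_adjusted"] == pytest.approx(p_t, rel=1e-6)

    def test_identical_groups_not_flagged(self):
        tk = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert not tk["significant"].any()

    def test_outlier_group_flags_exactly_its_pairs(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(0, 1, 20)
        g2 = rng.normal(0, 1, 20)
        g3 = rng.normal(10, 1, 20)
        tk = tukey_hsd([g1, g2, g3], alpha=0.05)
        flagged = {
            (row.group_a, row.group_b) for row in tk.itertuples() if row.significant
        }
        assert flagged == {(0, 2), (1, 2)}
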