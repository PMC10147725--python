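import numpy as np
import pandas as pd
import pytest

from wmnet import (
    ValidationError,
    kappa_from_confusion,
    lasso_select,
    leakage_audit,
    permutation_test_classifier,
    scale_minmax,
    svm_crossval,
)


def make_gaussian_features(
    rng, n_per_class=30, n_signal=3, n_noise=5, shift=3.0
):
    n = 2 * n_per_class
    x = rng.normal(size=(n, n_signal + n_noise))
    x[n_per_class:, :n_signal] += shift
    labels = np.array(["control"] * n_per_class + ["patient"] * n_per_class)
    cols = [f"s{i}" for i in range(n_signal)] + [
        f"noise{i}" for i in range(n_noise)
    ]
    return pd.DataFrame(x, columns=cols), labels


class TestScaleMinmax:
    def test_train_mapped_to_unit_interval_test_follows(self):
        train = np.array([[2.0], [4.0]])
        test = np.array([[3.0]])
        tr, te, keep = scale_minmax(train, test)
        np.testing.assert_allclose(tr.ravel(), [0.0, 1.0])
        assert te[0, 0] == pytest.approx(0.5)
        assert keep.all()

    def test_test_values_outside_train_range_not_clipped(self):
        tr, te, _ = scale_minmax(np.array([[2.0], [4.0]]), np.array([[5.0]]))
        assert te[0, 0] == pytest.approx(1.5)

    def test_constant_columns_dropped_with_warning(self, caplog):
        train = np.array([[1.0, 2.0], [1.0, 4.0]])
        with caplog.at_level("WARNING"):
            tr, te, keep = scale_minmax(train, train)
        assert keep.tolist() == [False, True]
        assert tr.shape[1] == 1

    def test_rescaling_scaled_train_is_identity(self):
        rng = np.random.default_rng(0)
        train = rng.random((10, 4))
        tr, _, _ = scale_minmax(train, train)
        tr2, _, _ = scale_minmax(tr, tr)
        np.testing.assert_allclose(tr2, tr, atol=1e-12)


class TestKappa:
    def test_perfect_diagonal_is_one(self):
        assert kappa_from_confusion([[50, 0], [0, 50]]) == pytest.approx(1.0)

    def test_balanced_accuracy_identity(self):
        # balanced two-class data: kappa = 2*accuracy - 1; at the printed
        # accuracy of 98.09% this gives the printed kappa of 96.18%
        acc = 0.9809
        n = 10_000
        correct = acc * n
        confusion = [[correct / 2, n / 2 - correct / 2],
                     [n / 2 - correct / 2, correct / 2]]
        kappa = kappa_from_confusion(confusion)
        assert kappa == pytest.approx(2 * acc - 1, abs=1e-12)
        assert round(100 * kappa, 2) == 96.18

    def test_random_confusion_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        pred = rng.integers(0, 2, 400)
        c = np.array(
            [[np.sum((y == i) & (pred == j)) for j in (0, 1)] for i in (0, 1)]
        )
        assert abs(kappa_from_confusion(c)) < 0.15

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValidationError):
            kappa_from_confusion([[0, 0], [0, 0]])


class TestLassoSelect:
    def test_single_separating_feature_selected(self):
        rng = np.random.default_rng(2)
        x, labels = make_gaussian_features(
            rng, n_per_class=25, n_signal=1, n_noise=4, shift=6.0
        )
        selected = lasso_select(x, labels, repeats=3, seed=0)
        assert "s0" in selected

    def test_signal_recovery_dominates_noise(self):
        good = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            x, labels = make_gaussian_features(
                rng, n_per_class=46, n_signal=5, n_noise=45, shift=2.0
            )
            selected = lasso_select(x, labels, repeats=3, seed=seed)
            n_signal = sum(1 for s in selected if s.startswith("s"))
            n_noise = len(selected) - n_signal
            if n_signal >= 4 and n_noise <= 10:
                good += 1
        assert good >= 2

    def test_null_labels_select_little_or_nothing(self):
        sizes = []
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            x = pd.DataFrame(
                rng.normal(size=(40, 12)),
                columns=[f"f{i}" for i in range(12)],
            )
            labels = np.array(["control", "patient"] * 20)
            try:
                sizes.append(len(lasso_select(x, labels, repeats=3, seed=seed)))
            except ValidationError:
                sizes.append(0)
        assert np.median(sizes) <= 4

    def test_too_few_features_rejected(self):
        x = pd.DataFrame({"only": np.arange(10.0)})
        with pytest.raises(ValidationError):
            lasso_select(x, np.array(["control", "patient"] * 5))


class TestSvmCrossval:
    def test_separable_classes_near_perfect(self):
        rng = np.random.default_rng(3)
        x, labels = make_gaussian_features(rng, shift=5.0)
        rep = svm_crossval(x, labels, repeats=5, seed=0)
        assert rep.accuracy >= 95.0
        assert rep.kappa >= 90.0
        assert rep.n_fold_evaluations == 25

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(4)
        x, labels = make_gaussian_features(rng, shift=0.0)
        rep = svm_crossval(x, labels, repeats=5, seed=0)
        assert abs(rep.accuracy - 50.0) < 15.0
        assert abs(rep.kappa) < 30.0

    def test_same_seed_identical_report(self):
        rng = np.random.default_rng(5)
        x, labels = make_gaussian_features(rng, shift=1.0)
        a = svm_crossval(x, labels, repeats=3, seed=7)
        b = svm_crossval(x, labels, repeats=3, seed=7)
        assert a == b

    def test_balanced_folds_accuracy_is_mean_of_recalls(self):
        rng = np.random.default_rng(6)
        x, labels = make_gaussian_features(rng, n_per_class=20, shift=1.5)
        rep = svm_crossval(x, labels, repeats=4, folds=4, seed=1)
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2, abs=1e-9
        )

    def test_weights_nonnegative_and_named(self):
        rng = np.random.default_rng(7)
        x, labels = make_gaussian_features(rng, shift=3.0)
        rep = svm_crossval(x, labels, repeats=2, seed=0)
        assert set(rep.feature_weights) == set(x.columns)
        assert all(w >= 0 for w in rep.feature_weights.values())


class TestPermutationTestClassifier:
    def test_strong_signal_reaches_floor(self):
        rng = np.random.default_rng(8)
        x, labels = make_gaussian_features(rng, shift=5.0)
        res = permutation_test_classifier(x, labels, n_perm=99, seed=0)
        assert res["perm_p"] == 0.0
        assert res["perm_p_smoothed"] == pytest.approx(1 / 100)

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(9)
        ps = []
        for seed in range(5):
            x, labels = make_gaussian_features(
                rng, n_per_class=10, shift=0.0, n_signal=1, n_noise=3
            )
            res = permutation_test_classifier(x, labels, n_perm=49, seed=seed)
            ps.append(res["perm_p_smoothed"])
        assert np.median(ps) > 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        x, labels = make_gaussian_features(rng, n_per_class=10, shift=1.0)
        a = permutation_test_classifier(x, labels, n_perm=29, seed=3)
        b = permutation_test_classifier(x, labels, n_perm=29, seed=3)
        assert a == b


class TestLeakageAudit:
    def test_report_names_headline_variant(self):
        rng = np.random.default_rng(11)
        x, labels = make_gaussian_features(
            rng, n_per_class=12, n_signal=1, n_noise=7, shift=0.0
        )
        audit = leakage_audit(
            x, labels, screen_alpha=0.3, cv_repeats=2, seed=0
        )
        assert audit.headline_variant == "pre-cv"
        assert 0 <= audit.accuracy_pre_cv <= 100
        assert 0 <= audit.accuracy_nested <= 100

    def test_signal_cohort_both_variants_beat_chance(self):
        rng = np.random.default_rng(12)
        x, labels = make_gaussian_features(
            rng, n_per_class=20, n_signal=3, n_noise=5, shift=3.0
        )
        audit = leakage_audit(
            x, labels, screen_alpha=0.1, cv_repeats=2, seed=0
        )
        assert audit.accuracy_pre_cv > 75.0
        assert audit.accuracy_nested > 75.0
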