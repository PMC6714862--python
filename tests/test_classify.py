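import numpy as np
import pytest

from eegemo.classify import (BASELINE_METHODS, ComparisonReport,
                             apply_normalizer, baseline, compare_methods,
                             fit_normalizer, loso_evaluate, st_sbssvm,
                             train_svm_rbf)
from eegemo.datasets import DegenerateClassError
from eegemo.features import FeatureMatrix
from eegemo.synthetic import generate_feature_table


class TestNormalizer:
    def test_hand_arithmetic(self):
        model = fit_normalizer(np.array([[0.0], [2.0]]))
        assert model.center[0] == 1.0 and model.scale[0] == 1.0
        np.testing.assert_array_equal(
            apply_normalizer(model, np.array([[4.0]])), [[3.0]])

    def test_training_rows_become_zero_mean_unit_scale(self):
        rows = np.random.default_rng(0).normal(5, 3, (50, 4))
        model = fit_normalizer(rows)
        z = apply_normalizer(model, rows)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-9)

    def test_constant_column_centered_with_warning(self):
        rows = np.column_stack([np.arange(4.0), np.full(4, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_normalizer(rows)
        z = apply_normalizer(model, rows)
        np.testing.assert_array_equal(z[:, 1], 0.0)


class TestSvmRbf:
    def test_separable_blobs(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 1, (100, 2)), rng.normal(3, 1, (100, 2))])
        y = np.repeat([0, 1], 100)
        clf = train_svm_rbf(X, y)
        assert (clf.predict(X) == y).mean() > 0.95

    def test_rbf_beats_linear_on_nonlinear_pattern(self):
        # alternating class stripes: no halfplane does better than chance,
        # an RBF boundary separates them cleanly
        rng = np.random.default_rng(0)
        blocks, labels = [], []
        for k in range(8):
            blocks.append(np.column_stack(
                [k + 0.5 + 0.15 * rng.standard_normal(30),
                 rng.uniform(0, 1, 30)]))
            labels.append(np.full(30, k % 2))
        X, y = np.vstack(blocks), np.concatenate(labels).astype(int)
        rbf_acc = (train_svm_rbf(X, y, C=10.0, gamma=1.0).predict(X)
                   == y).mean()
        from sklearn.svm import SVC

        lin_acc = (SVC(kernel="linear").fit(X, y).predict(X) == y).mean()
        assert rbf_acc > 0.9
        assert lin_acc <= 0.6

    def test_one_point_per_class(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1])
        clf = train_svm_rbf(X, y)
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateClassError):
            train_svm_rbf(np.zeros((4, 2)), np.ones(4))


class TestBaselines:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            baseline("gradient_hallucination")

    def test_pca_keeps_95pct_variance(self, informative_table):
        fm = informative_table
        pipe = baseline("pca_svm")
        pipe.fit(fm.values, fm.labels)
        assert pipe._pca.n_components == 0.95
        assert pipe._pca.explained_variance_ratio_.sum() >= 0.95

    @pytest.mark.parametrize("method", BASELINE_METHODS)
    def test_every_baseline_beats_chance_on_separable_features(
            self, method, informative_table):
        ev = loso_evaluate(informative_table,
                           baseline(method, random_state=0))
        assert ev.mean_accuracy > 0.8


class TestLoso:
    def test_one_fold_per_subject_partition(self, informative_table):
        fm = informative_table
        ev = loso_evaluate(fm, baseline("svm"))
        assert len(ev.fold_subjects) == len(np.unique(fm.subject_id))
        assert sorted(ev.fold_subjects) == sorted(np.unique(fm.subject_id))
        assert all(0 <= a <= 1 for a in ev.fold_accuracies)
        assert np.isclose(ev.mean_accuracy, np.mean(ev.fold_accuracies))

    def test_two_subjects_minimum(self):
        fm = generate_feature_table(n_subjects=1, n_trials=10, seed=0)
        with pytest.raises(ValueError):
            loso_evaluate(fm, baseline("svm"))

    def test_held_out_subject_rows_never_reach_training(
            self, informative_table):
        """The training data each fold sees must exclude the held-out
        subject: replacing that subject's features by a constant leaves
        its own fold's training inputs bit-identical."""
        fm = informative_table

        class SpyPipeline:
            def __init__(self):
                self.inner = baseline("svm")
                self.training_digests = []

            def fit(self, X, y, groups=None, column_names=None):
                self.training_digests.append(hash(X.tobytes()))
                return self.inner.fit(X, y, groups=groups)

            def predict(self, X):
                return self.inner.predict(X)

        corrupt_subject = fm.subject_id[0]
        values = fm.values.copy()
        values[fm.subject_id == corrupt_subject] = 777.0
        fm2 = FeatureMatrix(values, fm.column_names, fm.labels,
                            fm.subject_id)
        spy_ref, spy_cor = SpyPipeline(), SpyPipeline()
        ref = loso_evaluate(fm, spy_ref)
        loso_evaluate(fm2, spy_cor)
        for subj, d_ref, d_cor in zip(ref.fold_subjects,
                                      spy_ref.training_digests,
                                      spy_cor.training_digests):
            if subj == corrupt_subject:
                # this fold trains only on untouched subjects
                assert d_ref == d_cor
            else:
                # other folds do train on the corrupted rows
                assert d_ref != d_cor

    def test_chance_level_on_permuted_labels(self):
        fm = generate_feature_table(n_subjects=6, n_trials=20,
                                    n_features=20, n_informative=4,
                                    delta=2.0, seed=3)
        rng = np.random.default_rng(8)
        shuffled = FeatureMatrix(fm.values, fm.column_names,
                                 rng.permutation(fm.labels), fm.subject_id)
        ev = loso_evaluate(shuffled, baseline("svm"))
        assert 0.4 <= ev.mean_accuracy <= 0.6


class TestStSbsSvmPipeline:
    def test_recovers_informative_columns(self, informative_table):
        fm = informative_table
        ev = loso_evaluate(fm, st_sbssvm())
        assert ev.mean_accuracy > 0.85
        informative = {f"f{j:03d}" for j in range(5)}
        for selected in ev.fold_selected:
            assert informative & set(selected)

    def test_per_fold_filter_ignores_held_out_subject(self,
                                                      informative_table):
        """Filtering and SBS run inside the training fold, so corrupting
        the held-out subject's rows cannot change what that fold
        selects."""
        fm = informative_table
        ref = loso_evaluate(fm, st_sbssvm())
        corrupt_subject = fm.subject_id[-1]
        values = fm.values.copy()
        values[fm.subject_id == corrupt_subject] = -55.0
        fm2 = FeatureMatrix(values, fm.column_names, fm.labels,
                            fm.subject_id)
        corrupted = loso_evaluate(fm2, st_sbssvm())
        k = list(ref.fold_subjects).index(corrupt_subject)
        assert ref.fold_selected[k] == corrupted.fold_selected[k]


class TestComparisonReport:
    def test_from_differences_matches_hand_mean(self):
        report = ComparisonReport.from_differences(
            "st_sbssvm", {"svm": 17, "pca_svm": 17, "sbs": -0.42,
                          "knn": 10, "pca_knn": 11, "rf": 20})
        assert round(report.average_difference_pct, 1) == 12.4

    def test_from_accuracies(self):
        report = ComparisonReport.from_accuracies(
            "ref", {"ref": 0.72, "svm": 0.55})
        assert np.isclose(report.differences_pct["svm"], 17.0)
        assert np.isclose(report.average_difference_pct, 17.0)

    def test_method_identical_to_reference_has_zero_difference(self):
        fm = generate_feature_table(n_subjects=4, n_trials=10,
                                    n_features=10, n_informative=3,
                                    delta=1.5, seed=9)
        report = compare_methods(fm, methods=["svm"],
                                 reference=baseline("svm"))
        assert report.differences_pct["svm"] == 0.0

    def test_compare_methods_arithmetic_is_exact(self, informative_table):
        report = compare_methods(informative_table, methods=["svm", "knn"],
                                 reference=baseline("rf", random_state=1))
        for m in ("svm", "knn"):
            expected = (report.accuracies[report.reference]
                        - report.accuracies[m]) * 100.0
            assert report.differences_pct[m] == expected
        assert np.isclose(report.average_difference_pct,
                          np.mean(list(report.differences_pct.values())))
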