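"""Cross-validation protocol, metric conventions, improvement arithmetic."""

import numpy as np
import pytest

from vmdoc.classify import (CLASSIFIER_KINDS, ClassifierSpec, EvalReport,
                            absolute_improvement, metrics,
                            relative_improvement, run_cv)
from vmdoc.features import FeatureTable


def make_table(values, labels):
    values = np.asarray(values, float)
    return FeatureTable(values=values,
                        feature_names=[f"f{i}" for i in range(values.shape[1])],
                        labels=list(labels),
                        subject_ids=[f"s{i}" for i in range(values.shape[0])])


class TestMetrics:
    def test_balanced_binary_confusion(self):
        acc, prec, rec, f1 = metrics(np.array([[4, 1], [1, 4]]))
        assert (acc, prec, rec, f1) == (80.0, 80.0, 80.0, 80.0)

    def test_diagonal_is_perfect(self):
        acc, prec, rec, f1 = metrics(np.diag([3, 5, 2]))
        assert acc == prec == rec == f1 == 100.0

    def test_degenerate_column_convention(self):
        # one class never predicted: its precision counts as 0 in the macro
        with pytest.warns(RuntimeWarning, match="no predictions"):
            acc, prec, rec, f1 = metrics(np.array([[3, 0], [3, 0]]))
        assert acc == 50.0
        assert prec == 25.0
        assert rec == 50.0

    def test_symmetric_confusions_collapse_metrics(self):
        for c in (np.array([[7, 2], [2, 7]]), np.array([[5, 1, 1], [1, 5, 1], [1, 1, 5]])):
            acc, prec, rec, f1 = metrics(c)
            assert acc == pytest.approx(prec) == pytest.approx(rec) == pytest.approx(f1)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            metrics(np.zeros((2, 2)))


class TestRunCV:
    def test_separable_clusters_perfect_for_all_classifiers(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(10, 1, (20, 4))])
        table = make_table(x, ["UWS"] * 20 + ["MCS"] * 20)
        for kind in CLASSIFIER_KINDS:
            rep = run_cv(table, ClassifierSpec(kind=kind, random_seed=0), seed=0)
            assert rep.accuracy == 100.0

    def test_chance_level_under_label_permutation(self, rng):
        n = 45
        labels = rng.permutation(["coma"] * 15 + ["UWS"] * 15 + ["MCS"] * 15)
        table = make_table(rng.standard_normal((n, 20)), labels)
        # binomial 99% interval around 1/3 for n = 45
        half = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n)
        for kind in CLASSIFIER_KINDS:
            rep = run_cv(table, ClassifierSpec(kind=kind, random_seed=3), seed=3)
            assert 100 * (1 / 3 - half) <= rep.accuracy <= 100 * (1 / 3 + half)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((30, 6))
        x[15:] += 1.0
        table = make_table(x, ["UWS"] * 15 + ["MCS"] * 15)
        spec = ClassifierSpec(kind="ensemble_bagged_tree", random_seed=5)
        a = run_cv(table, spec, seed=5)
        b = run_cv(table, spec, seed=5)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)
        assert a.fold_assignment == b.fold_assignment

    def test_folds_partition_and_stratify(self, rng):
        x = rng.standard_normal((40, 4))
        table = make_table(x, ["UWS"] * 20 + ["MCS"] * 20)
        rep = run_cv(table, ClassifierSpec(kind="knn"), k_folds=10, seed=0)
        assert sorted(rep.fold_assignment) == sorted(table.subject_ids)
        counts = np.bincount(list(rep.fold_assignment.values()))
        assert counts.sum() == 40 and counts.max() - counts.min() <= 1

    def test_fold_reduction_warning(self, rng):
        x = rng.standard_normal((8, 3))
        table = make_table(x, ["UWS"] * 4 + ["MCS"] * 4)
        with pytest.warns(RuntimeWarning, match="reducing folds"):
            rep = run_cv(table, ClassifierSpec(kind="knn", knn_k=1), k_folds=10, seed=0)
        assert rep.n_folds == 4

    def test_single_class_raises(self, rng):
        table = make_table(rng.standard_normal((10, 3)), ["MCS"] * 10)
        with pytest.raises(ValueError, match="2 classes"):
            run_cv(table, ClassifierSpec(kind="knn"))

    def test_nan_features_raise(self):
        x = np.ones((10, 2))
        x[3, 1] = np.nan
        table = make_table(x, ["UWS"] * 5 + ["MCS"] * 5)
        with pytest.raises(ValueError, match="non-finite"):
            run_cv(table, ClassifierSpec(kind="knn"))

    def test_in_fold_selection_reduces_columns(self, rng):
        x = rng.standard_normal((30, 10))
        x[15:, 0] += 4.0
        table = make_table(x, ["UWS"] * 15 + ["MCS"] * 15)
        from vmdoc.stats import kw_mask
        rep = run_cv(table, ClassifierSpec(kind="knn"), seed=0,
                     feature_selector=lambda xs, ys: kw_mask(xs, ys, 0.05))
        assert rep.n_features_used < 10


class TestImprovementArithmetic:
    @pytest.mark.parametrize("new,ref,expect", [
        (76.0, 42.5, 78.8),
        (86.7, 53.3, 62.7),
        (80.5, 53.5, 50.5),
        (60.0, 60.0, 0.0),
    ])
    def test_relative_improvement_to_one_decimal(self, new, ref, expect):
        assert round(relative_improvement(new, ref), 1) == expect

    def test_relative_improvement_three_significant_figures(self):
        assert float(f"{relative_improvement(83.3, 36.7):.3g}") == 127

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            relative_improvement(50.0, 0.0)

    @pytest.mark.parametrize("sel,all_,expect", [
        (80.5, 76.0, 4.5), (57.5, 73.5, -16.0), (42.0, 42.0, 0.0),
    ])
    def test_absolute_improvement(self, sel, all_, expect):
        assert absolute_improvement(sel, all_) == pytest.approx(expect)


class TestClassifierSpec:
    @pytest.mark.parametrize("kwargs", [
        {"kind": "mlp"}, {"knn_k": 0}, {"ebt_n_trees": 1},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierSpec(**kwargs)

    def test_builders_produce_fitted_estimators(self, rng):
        x, y = rng.standard_normal((20, 3)), ["a"] * 10 + ["b"] * 10
        for kind in CLASSIFIER_KINDS:
            clf = ClassifierSpec(kind=kind).build()
            clf.fit(x, y)
            assert set(clf.predict(x)) <= {"a", "b"}
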