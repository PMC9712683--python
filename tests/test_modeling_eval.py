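import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

import afpkit as a
from afpkit.modeling_eval import confusion_from_scores

from conftest import make_signal_matrix


def counts_to_arrays(tp, tn, fp, fn):
    y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
    y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
    return np.array(y_true), np.array(y_pred)


def mann_whitney_auroc(scores, labels):
    """Rank-statistic formulation of the area under the ROC curve."""
    ranks = rankdata(scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        rep = a.compute_metrics(a.ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (rep.acc, rep.sn, rep.sp, rep.mcc, rep.f_measure) == (1, 1, 1, 1, 1)

    def test_perfect_inversion(self):
        rep = a.compute_metrics(a.ConfusionCounts(tp=0, tn=0, fp=50, fn=50))
        assert rep.acc == 0
        assert rep.mcc == -1

    def test_worked_example(self):
        rep = a.compute_metrics(a.ConfusionCounts(tp=40, tn=45, fp=5, fn=10))
        assert rep.acc == pytest.approx(0.85)
        assert rep.sn == pytest.approx(0.8)
        assert rep.sp == pytest.approx(0.9)
        assert rep.precision == pytest.approx(8 / 9)
        assert rep.mcc == pytest.approx(0.7035, abs=5e-5)

    def test_zero_marginal_mcc_is_zero(self):
        rep = a.compute_metrics(a.ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert rep.mcc == 0.0

    def test_all_zero_confusion_rejected(self):
        with pytest.raises(ValueError):
            a.compute_metrics(a.ConfusionCounts(0, 0, 0, 0))

    def test_matches_independent_implementation_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            rep = a.compute_metrics(a.ConfusionCounts(tp, tn, fp, fn))
            y_true, y_pred = counts_to_arrays(tp, tn, fp, fn)
            assert rep.acc == pytest.approx(accuracy_score(y_true, y_pred))
            assert rep.sn == pytest.approx(
                recall_score(y_true, y_pred, zero_division=0)
            )
            assert rep.precision == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0)
            )
            assert rep.f_measure == pytest.approx(
                f1_score(y_true, y_pred, zero_division=0)
            )
            if min(tp + fn, tp + fp, tn + fn, tn + fp) > 0:
                assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))


class TestRocPr:
    def test_perfect_separation(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.linspace(0, 1, 10)
        curves = a.roc_and_pr(scores, labels)
        assert curves.auroc == pytest.approx(1.0)
        assert curves.aupr == pytest.approx(1.0)

    def test_constant_scores_give_chance_auroc(self):
        labels = np.array([0, 1] * 10)
        curves = a.roc_and_pr(np.full(20, 0.5), labels)
        assert curves.auroc == pytest.approx(0.5)

    def test_label_independent_scores_near_chance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=2000)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, size=2000)
        scores = rng.uniform(size=2000)
        assert a.roc_and_pr(scores, labels).auroc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            a.roc_and_pr(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_auroc_equals_rank_statistic(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            assert a.roc_and_pr(scores, labels).auroc == pytest.approx(
                mann_whitney_auroc(scores, labels), abs=1e-10
            )


class TestStratifiedKFold:
    def test_balanced_exact_division(self):
        labels = np.array([1] * 50 + [0] * 50)
        folds = a.stratified_kfold(labels, k=10, seed=0)
        for fold in range(10):
            mask = folds == fold
            assert mask.sum() == 10
            assert labels[mask].sum() == 5

    def test_fold_sizes_differ_by_at_most_one(self):
        labels = np.array([1] * 51 + [0] * 52)
        folds = a.stratified_kfold(labels, k=10, seed=0)
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 103

    def test_deterministic(self):
        labels = np.array([1, 0] * 30)
        assert np.array_equal(
            a.stratified_kfold(labels, k=5, seed=3),
            a.stratified_kfold(labels, k=5, seed=3),
        )

    def test_class_smaller_than_k(self):
        labels = np.array([1] * 3 + [0] * 50)
        with pytest.raises(ValueError, match="fewer than k"):
            a.stratified_kfold(labels, k=10, seed=0)

    def test_leave_one_out_boundary(self):
        labels = np.array([1, 0] * 10)
        folds = a.stratified_kfold(labels, k=20, seed=0)
        assert sorted(folds) == list(range(20))


class TestTrainPredict:
    @pytest.mark.parametrize("kind", ["RF", "ERT", "LXGB"])
    def test_separable_training_accuracy(self, kind):
        rng = np.random.default_rng(0)
        matrix, _ = make_signal_matrix(rng, n_features=2, n_informative=2, shift=6.0)
        config = a.ModelConfig(kind=kind, n_estimators=50, seed=0)
        model = a.train(matrix, config)
        scores = a.predict_scores(model, matrix)
        assert np.array_equal((scores >= 0.5).astype(int), matrix.labels)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        matrix, _ = make_signal_matrix(rng)
        matrix.labels = np.zeros_like(matrix.labels)
        with pytest.raises(ValueError, match="both classes"):
            a.train(matrix, a.ModelConfig(n_estimators=10))

    def test_determinism_same_seed_same_predictions(self):
        rng = np.random.default_rng(2)
        matrix, _ = make_signal_matrix(rng)
        config = a.ModelConfig(kind="LXGB", n_estimators=60, seed=5)
        s1 = a.predict_scores(a.train(matrix, config), matrix)
        s2 = a.predict_scores(a.train(matrix, config), matrix)
        assert np.array_equal(s1, s2)

    def test_name_mismatch_lists_difference(self):
        rng = np.random.default_rng(3)
        matrix, _ = make_signal_matrix(rng, n_features=4)
        model = a.train(matrix, a.ModelConfig(n_estimators=10))
        renamed = a.FeatureMatrix(
            record_ids=matrix.record_ids,
            names=["g0"] + matrix.names[1:],
            values=matrix.values,
            labels=matrix.labels,
        )
        with pytest.raises(ValueError, match="f00"):
            a.predict_scores(model, renamed)

    def test_shuffled_columns_same_scores(self):
        """Scores are name-aligned, not position-aligned."""
        rng = np.random.default_rng(4)
        matrix, _ = make_signal_matrix(rng, n_features=6)
        model = a.train(matrix, a.ModelConfig(kind="LXGB", n_estimators=40, seed=0))
        perm = rng.permutation(6)
        shuffled = a.FeatureMatrix(
            record_ids=matrix.record_ids,
            names=[matrix.names[j] for j in perm],
            values=matrix.values[:, perm],
            labels=matrix.labels,
        )
        assert np.array_equal(
            a.predict_scores(model, matrix), a.predict_scores(model, shuffled)
        )

    def test_empty_matrix_empty_scores(self):
        rng = np.random.default_rng(5)
        matrix, _ = make_signal_matrix(rng, n_features=3)
        model = a.train(matrix, a.ModelConfig(n_estimators=10))
        empty = matrix.subset_rows(np.zeros(matrix.n_records, dtype=bool))
        assert a.predict_scores(model, empty).size == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            a.ModelConfig(kind="SVM")
        with pytest.raises(ValueError):
            a.ModelConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            a.ModelConfig(n_estimators=0)


class TestCrossValidate:
    def test_pooled_confusion_sums_to_dataset_size(self):
        rng = np.random.default_rng(0)
        matrix, _ = make_signal_matrix(rng, n_records=80)
        report = a.cross_validate(matrix, a.ModelConfig(n_estimators=40), k=5, seed=0)
        assert report.confusion.total == 80
        assert report.fold_breakdown is not None
        assert sum(r.confusion.total for r in report.fold_breakdown) == 80

    def test_strong_signal_high_accuracy(self):
        rng = np.random.default_rng(1)
        matrix, _ = make_signal_matrix(rng, n_records=200, n_features=10, shift=3.0)
        report = a.cross_validate(matrix, a.ModelConfig(n_estimators=60), k=5, seed=0)
        assert report.acc > 0.9
        assert report.auroc > 0.95

    def test_null_signal_near_chance(self):
        accs = []
        for rep in range(5):
            rng = np.random.default_rng(300 + rep)
            matrix, _ = make_signal_matrix(
                rng, n_records=200, n_features=10, n_informative=0
            )
            report = a.cross_validate(
                matrix, a.ModelConfig(n_estimators=40, seed=rep), k=5, seed=rep
            )
            accs.append(report.acc)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_leave_one_out_runs(self):
        rng = np.random.default_rng(2)
        matrix, _ = make_signal_matrix(rng, n_records=20, n_features=3)
        report = a.cross_validate(matrix, a.ModelConfig(kind="ERT", n_estimators=20), k=20, seed=0)
        assert report.confusion.total == 20
        assert report.auroc is not None


class TestImbalanceAblation:
    def test_smoke_all_metrics_finite(self):
        rng = np.random.default_rng(0)
        matrix, _ = make_signal_matrix(rng, n_records=60, n_features=5)
        reports = a.imbalance_ablation(
            matrix, {"1:1": (10, 10)}, a.ModelConfig(n_estimators=20), k=2, seed=0
        )
        rep = reports["1:1"]
        for value in (rep.acc, rep.sn, rep.sp, rep.mcc, rep.auroc, rep.aupr):
            assert np.isfinite(value)
        assert rep.metadata["ratio"] == "1:1"

    def test_insufficient_pool_names_shortfall(self):
        rng = np.random.default_rng(1)
        matrix, _ = make_signal_matrix(rng, n_records=40)
        with pytest.raises(ValueError, match="negatives"):
            a.imbalance_ablation(
                matrix, {"1:3": (10, 900)}, a.ModelConfig(n_estimators=10), k=2, seed=0
            )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        matrix, _ = make_signal_matrix(rng, n_records=80)
        kwargs = dict(
            ratios={"1:1": (15, 15)}, config=a.ModelConfig(n_estimators=20), k=3, seed=9
        )
        r1 = a.imbalance_ablation(matrix, **kwargs)["1:1"]
        r2 = a.imbalance_ablation(matrix, **kwargs)["1:1"]
        assert r1.to_dict() == r2.to_dict()
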