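import numpy as np
import pytest

from lbpnet import EvalConfig, evaluate, run_protocol, stratified_split, train_svm
from conftest import FAST_ENET, fast_eval


class StubModel:
    """Deterministic stand-in classifier for confusion/AUC arithmetic."""

    def __init__(self, predictions, decisions, positive="HC"):
        self.predictions = np.asarray(predictions)
        self.decisions = np.asarray(decisions, dtype=float)
        self.feature_indices_ = np.array([0])
        self.named_steps = {"svm": self}
        self.classes_ = np.array(sorted(set(self.predictions) | {positive}))

    def predict(self, X):
        return self.predictions

    def decision_function(self, X):
        # signed toward classes_[1], mirroring sklearn convention
        return self.decisions


def stub_inputs(n):
    return np.zeros((n, 1))


class TestStratifiedSplit:
    def test_study_sizes_split_70_30(self):
        y = np.array(["HC"] * 27 + ["LBP"] * 24)
        tr, te = stratified_split(y, 0.70, seed=0)
        assert (y[tr] == "HC").sum() == 19 and (y[tr] == "LBP").sum() == 17
        assert (y[te] == "HC").sum() == 8 and (y[te] == "LBP").sum() == 7
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 51

    def test_even_split(self):
        y = np.array(["A"] * 10 + ["B"] * 10)
        tr, te = stratified_split(y, 0.5, seed=1)
        assert (y[tr] == "A").sum() == 5 and (y[te] == "B").sum() == 5

    def test_deterministic_given_seed(self):
        y = np.array(["A"] * 9 + ["B"] * 7)
        assert np.array_equal(
            stratified_split(y, 0.7, seed=42)[0], stratified_split(y, 0.7, seed=42)[0]
        )

    def test_rejects_class_emptying_split(self):
        y = np.array(["A"] * 2 + ["B"] * 10)
        with pytest.raises(ValueError, match="empty"):
            stratified_split(y, 0.9, seed=0)


class TestEvaluate:
    def test_worked_confusion_example(self):
        """TP=10, TN=6, FP=2, FN=2 -> accuracy 0.80, sensitivity 10/12,
        specificity 6/8."""
        y = np.array(["HC"] * 12 + ["LBP"] * 8)
        pred = np.array(["HC"] * 10 + ["LBP"] * 2 + ["LBP"] * 6 + ["HC"] * 2)
        dv = np.where(pred == "HC", 1.0, -1.0) * -1  # toward classes_[1]=LBP
        res = evaluate(StubModel(pred, dv), stub_inputs(20), y, positive_class="HC")
        assert (res.tp, res.tn, res.fp, res.fn) == (10, 6, 2, 2)
        assert res.accuracy == pytest.approx(0.80)
        assert res.sensitivity == pytest.approx(10 / 12)
        assert res.specificity == pytest.approx(6 / 8)
        assert res.tp + res.fp + res.tn + res.fn == 20

    def test_perfect_decision_values_give_auc_one(self):
        y = np.array(["HC"] * 3 + ["LBP"] * 3)
        pred = y.copy()
        dv = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])  # toward LBP
        res = evaluate(StubModel(pred, dv), stub_inputs(6), y, positive_class="HC")
        assert res.auc == 1.0

    def test_tied_decision_values_give_auc_half(self):
        y = np.array(["HC"] * 3 + ["LBP"] * 3)
        res = evaluate(
            StubModel(y, np.zeros(6)), stub_inputs(6), y, positive_class="HC"
        )
        assert res.auc == 0.5

    def test_one_class_test_set_marks_auc_undefined(self):
        y = np.array(["HC"] * 4)
        res = evaluate(
            StubModel(y, np.ones(4)), stub_inputs(4), y, positive_class="HC"
        )
        assert np.isnan(res.auc)
        assert res.accuracy == 1.0

    def test_label_swap_symmetry(self):
        """Renaming the two classes consistently in truth and predictions
        (decision values untouched) swaps sensitivity/specificity and maps
        AUC to 1 - AUC."""
        rng = np.random.default_rng(0)
        y = np.array(["HC"] * 6 + ["LBP"] * 6)
        pred = rng.permutation(y)
        dv = rng.standard_normal(12)
        swap = {"HC": "LBP", "LBP": "HC"}
        y_sw = np.array([swap[v] for v in y])
        pred_sw = np.array([swap[v] for v in pred])
        a = evaluate(StubModel(pred, dv), stub_inputs(12), y, positive_class="HC")
        b = evaluate(StubModel(pred_sw, dv), stub_inputs(12), y_sw, positive_class="HC")
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)
        assert a.auc == pytest.approx(1 - b.auc)


class TestTrainSVM:
    def _separable(self, n=20):
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        X = np.column_stack(
            [np.where(y == "A", -2.0, 2.0), np.where(y == "A", 1.0, -1.0)]
        )
        X += np.random.default_rng(0).standard_normal(X.shape) * 0.05
        return X, y

    def test_separable_data_fits_perfectly(self):
        X, y = self._separable()
        cfg = EvalConfig(cost_grid=tuple(range(1, 11)), cv_repeats=2)
        model, cost = train_svm(X, y, np.array([0, 1]), cfg, cv_seed=0)
        assert model.score(X[:, model.feature_indices_], y) == 1.0
        assert cost in range(1, 11)

    def test_duplicated_training_set_same_cost(self):
        X, y = self._separable()
        cfg = EvalConfig(cost_grid=(1, 5, 10), cv_repeats=2)
        _, c1 = train_svm(X, y, np.array([0, 1]), cfg, cv_seed=3)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        _, c2 = train_svm(X2, y2, np.array([0, 1]), cfg, cv_seed=3)
        assert c1 == c2

    def test_zero_variance_features_dropped_with_warning(self):
        X, y = self._separable()
        X = np.column_stack([X, np.full(len(y), 3.14)])
        cfg = EvalConfig(cost_grid=(1,))
        with pytest.warns(UserWarning, match="zero-variance"):
            model, _ = train_svm(X, y, np.array([0, 1, 2]), cfg)
        assert np.array_equal(model.feature_indices_, [0, 1])

    def test_all_degenerate_features_fail(self):
        y = np.array(["A", "A", "B", "B"])
        X = np.ones((4, 2))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero variance"):
                train_svm(X, y, np.array([0, 1]), EvalConfig(cost_grid=(1,)))

    def test_empty_feature_list_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValueError, match="empty"):
            train_svm(X, y, np.array([], dtype=int), EvalConfig(cost_grid=(1,)))


class TestRunProtocol:
    def test_single_iteration_report_equals_iteration(self, effect_features):
        X, y = effect_features
        cfg = fast_eval(n_iterations=1, seed=5)
        rep = run_protocol(
            X.to_numpy(), y.to_numpy(), cfg, selector="enet", enet_cfg=FAST_ENET
        )
        (it,) = rep.per_iteration
        assert rep.mean_accuracy == it.accuracy
        assert rep.mean_auc == it.auc
        assert rep.selection_counts.sum() == len(it.selected_features)

    def test_deterministic_given_seed(self, effect_features):
        X, y = effect_features
        cfg = fast_eval(n_iterations=2, seed=7)
        r1 = run_protocol(X.to_numpy(), y.to_numpy(), cfg, selector="enet", enet_cfg=FAST_ENET)
        r2 = run_protocol(X.to_numpy(), y.to_numpy(), cfg, selector="enet", enet_cfg=FAST_ENET)
        assert r1.summary() == r2.summary()
        assert r1.selection_counts.equals(r2.selection_counts)

    def test_confusion_identities_every_iteration(self, effect_features):
        X, y = effect_features
        cfg = fast_eval(n_iterations=5, seed=1)
        rep = run_protocol(X.to_numpy(), y.to_numpy(), cfg, selector="enet", enet_cfg=FAST_ENET)
        for it in rep.per_iteration:
            total = it.tp + it.fp + it.tn + it.fn
            assert total == 14  # 25+25 at ratio 0.7: 18 train / 7 test per class
            assert it.accuracy == pytest.approx((it.tp + it.tn) / total)
            assert it.sensitivity == pytest.approx(it.tp / (it.tp + it.fn))
            assert it.specificity == pytest.approx(it.tn / (it.tn + it.fp))

    def test_selection_counts_support_topk_report(self, effect_features):
        X, y = effect_features
        cfg = fast_eval(n_iterations=4, seed=2)
        rep = run_protocol(
            X.to_numpy(), y.to_numpy(), cfg, selector="enet_subset", enet_cfg=FAST_ENET
        )
        total_selected = sum(len(it.selected_features) for it in rep.per_iteration)
        assert rep.selection_counts.sum() == total_selected
        top = rep.top_features(60)
        assert len(top) == 60
        assert top.iloc[0] == rep.selection_counts.max()

    def test_unknown_selector_aborts_with_iteration_index(self, effect_features):
        X, y = effect_features
        with pytest.raises(RuntimeError, match="iteration 0"):
            run_protocol(X.to_numpy(), y.to_numpy(), fast_eval(n_iterations=1), selector="pca")
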