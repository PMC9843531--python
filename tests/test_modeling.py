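"""Model grid, evaluation metrics, ranking, ensemble, leakage guard."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from navscreen.modeling import (
    ConfusionMatrix,
    EvalReport,
    LeakageError,
    accuracy,
    confusion_from_predictions,
    ensemble_vote,
    evaluate,
    fit_with_gridsearch,
    make_spec,
    mcc,
    rank_models,
    score_curves,
    sensitivity,
    specificity,
    top_k,
)


def brute_force_metrics(tp, fp, tn, fn):
    """Direct transcription of the metric formulas with 0-division -> 0."""
    n = tp + fp + tn + fn
    q = (tp + tn) / n if n else 0.0
    se = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    m = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return q, se, sp, m


class TestMetrics:
    def test_worked_confusion_matrix(self):
        cm = ConfusionMatrix(tp=82, fn=9, tn=96, fp=4)
        assert accuracy(cm) == pytest.approx(178 / 191)
        assert mcc(cm) == pytest.approx(0.8644, abs=2e-4)

    def test_perfect_predictions(self):
        cm = ConfusionMatrix(tp=10, fp=0, tn=15, fn=0)
        assert (accuracy(cm), sensitivity(cm), specificity(cm), mcc(cm)) \
            == (1.0, 1.0, 1.0, 1.0)

    def test_all_positive_degenerate_classifier(self):
        cm = confusion_from_predictions([1, 1, 0, 0], [1, 1, 1, 1])
        assert specificity(cm) == 0.0
        assert mcc(cm) == 0.0

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(*[st.integers(0, 40) for _ in range(4)])
    def test_metrics_match_brute_force(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        q, se, sp, m = brute_force_metrics(tp, fp, tn, fn)
        assert accuracy(cm) == pytest.approx(q)
        assert sensitivity(cm) == pytest.approx(se)
        assert specificity(cm) == pytest.approx(sp)
        assert mcc(cm) == pytest.approx(m)

    def test_mcc_agrees_with_sklearn_on_predictions(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            y = rng.integers(0, 2, size=60)
            p = rng.integers(0, 2, size=60)
            if len(set(y.tolist())) < 2:
                continue
            assert mcc(confusion_from_predictions(y, p)) == pytest.approx(
                matthews_corrcoef(y, p), abs=1e-12)


class TestScoreCurves:
    def test_perfect_ranking(self):
        labels = [0, 0, 1, 1]
        roc_auc, pr_auc, _, _ = score_curves([0.1, 0.2, 0.8, 0.9], labels)
        assert roc_auc == 1.0
        assert pr_auc == pytest.approx(1.0)

    def test_score_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        auc_fwd, _, _, _ = score_curves(scores, labels)
        auc_rev, _, _, _ = score_curves(-scores, labels)
        assert auc_fwd == pytest.approx(1.0 - auc_rev)

    def test_roc_auc_equals_pairwise_concordance(self):
        """Trapezoid ROC AUC equals the Mann-Whitney U statistic."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)   # ties included
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
            roc_auc, _, _, _ = score_curves(scores, labels)
            assert roc_auc == pytest.approx(np.mean(pairs), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            score_curves([0.1, 0.9], [1, 1])


class TestRanking:
    @staticmethod
    def _report(name, mcc_value, roc=0.9):
        cm = ConfusionMatrix(tp=1, fp=1, tn=1, fn=1)
        return EvalReport(model_name=name, eval_set="validation", cm=cm,
                          q=0.5, se=0.5, sp=0.5, mcc=mcc_value, roc_auc=roc,
                          pr_auc=0.5)

    def test_descending_by_mcc(self):
        reports = [self._report("a", 0.3), self._report("b", 0.9),
                   self._report("c", 0.5)]
        assert [r.model_name for r in rank_models(reports)] == ["b", "c", "a"]

    def test_tie_broken_by_roc_auc_then_name(self):
        reports = [self._report("z", 0.5, roc=0.88),
                   self._report("a", 0.5, roc=0.91),
                   self._report("b", 0.5, roc=0.88)]
        assert [r.model_name for r in rank_models(reports)] == ["a", "b", "z"]

    def test_top_k_sizes(self):
        reports = [self._report(f"m{i:02d}", i / 30) for i in range(30)]
        assert len(top_k(reports, 10)) == 10
        assert len(top_k(reports, 5)) == 5

    def test_mixed_eval_sets_rejected(self):
        r1 = self._report("a", 0.5)
        r2 = self._report("b", 0.5)
        r2.eval_set = "test"
        with pytest.raises(ValueError):
            rank_models([r1, r2])


class TestEnsemble:
    def test_majority_examples(self):
        votes = np.array([[1], [1], [0], [1], [0]])
        assert ensemble_vote(votes).tolist() == [1]
        assert ensemble_vote(np.array([[0], [0], [0], [0], [1]])).tolist() == [0]
        assert ensemble_vote(np.ones((5, 3), dtype=int)).tolist() == [1, 1, 1]

    def test_even_committee_rejected(self):
        with pytest.raises(ValueError):
            ensemble_vote(np.zeros((4, 2), dtype=int))


def _planted_features(rng, n, informative_col=True):
    X = rng.integers(0, 2, size=(n, 32))
    y = rng.integers(0, 2, size=n)
    if informative_col:
        X[:, 0] = y
    return X.astype(np.uint8), y


class TestGridSearch:
    def test_separable_signal_reaches_perfect_training_mcc(self):
        rng = np.random.default_rng(0)
        X, y = _planted_features(rng, 120)
        spec = make_spec("random_forest", "ecfp4",
                         grid={"n_estimators": [100], "max_depth": [None]})
        model = fit_with_gridsearch(spec, X, y, [f"id{i}" for i in range(120)])
        cm = confusion_from_predictions(y, model.estimator.predict(X))
        assert mcc(cm) == 1.0

    def test_grid_of_one_equals_direct_fit(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        X, y = _planted_features(rng, 80)
        spec = make_spec("logistic_regression", "maccs", grid={"C": [1.0]})
        model = fit_with_gridsearch(spec, X, y, [f"id{i}" for i in range(80)])
        direct = LogisticRegression(max_iter=5000, solver="liblinear",
                                    random_state=0, C=1.0).fit(X, y)
        assert np.array_equal(model.estimator.predict(X), direct.predict(X))
        assert model.best_params == {"C": 1.0}

    def test_hyperparameter_selection_is_deterministic(self):
        rng = np.random.default_rng(2)
        X, y = _planted_features(rng, 100, informative_col=False)
        ids = [f"id{i}" for i in range(100)]
        spec = make_spec("svm", "maccs", seed=3)
        assert (fit_with_gridsearch(spec, X, y, ids).best_params
                == fit_with_gridsearch(spec, X, y, ids).best_params)

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            fit_with_gridsearch(make_spec("naive_bayes", "maccs"),
                                X, np.ones(10, dtype=int),
                                [f"i{k}" for k in range(10)])


class TestSerialization:
    def test_model_survives_save_load_round_trip(self, tmp_path):
        from navscreen.modeling import load_model, save_model

        rng = np.random.default_rng(8)
        X, y = _planted_features(rng, 60)
        spec = make_spec("logistic_regression", "maccs", grid={"C": [1.0]})
        model = fit_with_gridsearch(spec, X, y, [f"id{i}" for i in range(60)])
        path = tmp_path / f"{model.name}.model"
        save_model(model, path)
        restored = load_model(path)
        assert restored.name == model.name
        assert np.array_equal(restored.estimator.predict(X),
                              model.estimator.predict(X))


class TestLeakageGuard:
    def test_overlapping_ids_hard_fail(self):
        rng = np.random.default_rng(5)
        X, y = _planted_features(rng, 60)
        ids = [f"id{i}" for i in range(60)]
        spec = make_spec("naive_bayes", "maccs")
        model = fit_with_gridsearch(spec, X, y, ids)
        with pytest.raises(LeakageError):
            evaluate(model, X[:10], y[:10], ids[:10], eval_set="validation")

    def test_disjoint_ids_pass(self):
        rng = np.random.default_rng(6)
        X, y = _planted_features(rng, 80)
        y[:2] = [0, 1]
        spec = make_spec("naive_bayes", "maccs")
        model = fit_with_gridsearch(spec, X[:60], y[:60],
                                    [f"id{i}" for i in range(60)])
        report = evaluate(model, X[60:], y[60:],
                          [f"id{i}" for i in range(60, 80)], eval_set="test")
        assert 0.0 <= report.q <= 1.0
        assert -1.0 <= report.mcc <= 1.0
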