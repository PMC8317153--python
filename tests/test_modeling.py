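"""Metrics, cross-validation, greedy feature selection and model bundles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef, precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from graphsig.modeling import (
    ModelBundle,
    auc_rank,
    cross_validate,
    evaluate_metrics,
    greedy_select,
    make_estimator,
    train_model,
    trimmed_evaluation,
)


def brute_force_auc(y, score):
    """Concordant-pair count oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = score[y == 1]
    neg = score[y == 0]
    conc = sum((p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg))
    return conc / (len(pos) * len(neg))


class TestEvaluateMetrics:
    def test_perfect_binary_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        m = evaluate_metrics(y, y.astype(float), "classification")
        assert m["mcc"] == pytest.approx(1.0)
        assert m["fpr"] == 0.0
        assert m["accuracy"] == 1.0 and m["sensitivity"] == 1.0

    def test_reversed_scores_auc_zero(self):
        y = np.array([0, 0, 1, 1])
        m = evaluate_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]), "classification")
        assert m["auc"] == 0.0

    def test_auc_equals_concordant_pair_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.integers(0, 2, 40)
            if len(set(y)) < 2:
                continue
            score = rng.normal(size=40).round(1)  # rounding forces ties
            assert auc_rank(y, score) == pytest.approx(brute_force_auc(y, score))

    def test_auc_rank_equals_trapezoidal_roc(self):
        # rank statistic vs sklearn's trapezoidal ROC integration
        rng = np.random.default_rng(17)
        for _ in range(10):
            y = rng.integers(0, 2, 50)
            if len(set(y)) < 2:
                continue
            score = rng.random(50)
            assert auc_rank(y, score) == pytest.approx(roc_auc_score(y, score))

    def test_confusion_metrics_match_sklearn(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        score = rng.random(60)
        m = evaluate_metrics(y, score, "classification")
        hard = (score >= 0.5).astype(int)
        assert m["mcc"] == pytest.approx(matthews_corrcoef(y, hard))
        assert m["precision"] == pytest.approx(precision_score(y, hard, zero_division=0))

    def test_mcc_invariant_under_label_swap(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 50)
        score = rng.random(50)
        a = evaluate_metrics(y, score, "classification")["mcc"]
        b = evaluate_metrics(1 - y, 1 - score, "classification")["mcc"]
        assert a == pytest.approx(b)

    def test_single_class_auc_is_nan_not_zero(self):
        m = evaluate_metrics(np.ones(5), np.random.default_rng(0).random(5), "classification")
        assert np.isnan(m["auc"])

    def test_regression_metrics(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate_metrics(y, y, "regression")
        assert m["pearson"] == pytest.approx(1.0)
        assert m["kendall"] == pytest.approx(1.0)
        assert m["rmse"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics([0, 1], [0.1], "classification")


class TestTrimmedEvaluation:
    def test_perfect_predictions_unchanged(self):
        y = np.linspace(0, 1, 20)
        m = trimmed_evaluation(y, y)
        assert m["pearson"] == pytest.approx(1.0)
        assert m["trimmed"] == 1.0

    def test_retains_exactly_ceil_90_percent(self):
        rng = np.random.default_rng(1)
        for n in (10, 11, 99, 100):
            y = rng.normal(size=n)
            m = trimmed_evaluation(y, y + rng.normal(size=n))
            assert m["n_retained"] == n - int(np.ceil(0.10 * n))

    def test_gross_outlier_removed_improves_pearson(self):
        rng = np.random.default_rng(4)
        y = np.linspace(0, 10, 50)
        pred = y + rng.normal(0, 0.1, 50)
        pred[25] += 40.0  # one gross outlier
        untrimmed = evaluate_metrics(y, pred, "regression")["pearson"]
        trimmed = trimmed_evaluation(y, pred)["pearson"]
        assert trimmed > untrimmed

    def test_small_n_refused_with_flag(self):
        y = np.arange(5.0)
        with pytest.warns(UserWarning, match="trimming refused"):
            m = trimmed_evaluation(y, y + 1)
        assert m["trimmed"] == 0.0
        assert m["n_retained"] == 5


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(21)
    n = 100
    y = rng.integers(0, 2, n).astype(float)
    X = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"noise{i}" for i in range(20)])
    X.insert(3, "oracle", y + rng.normal(0, 0.01, n))
    return X, y


class TestCrossValidate:
    def test_perfect_features_give_perfect_metrics(self, separable_data):
        X, y = separable_data
        report = cross_validate(X[["oracle", "noise0"]], y, "classification", k=5, seed=0)
        assert report.pooled["auc"] == pytest.approx(1.0)
        assert report.pooled["accuracy"] == 1.0

    def test_every_sample_predicted_once(self, separable_data):
        X, y = separable_data
        report = cross_validate(X, y, "classification", k=5, seed=0)
        assert not np.isnan(report.y_oof).any()
        assert len(report.per_fold) == 5

    def test_stratification_failure_reported(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)), columns=list("abc"))
        y = np.array([1.0] * 3 + [0.0] * 17)
        with pytest.raises(ValueError, match="stratification"):
            cross_validate(X, y, "classification", k=10, seed=0)

    def test_nan_features_rejected_with_columns(self, separable_data):
        X, y = separable_data
        X = X.copy()
        X.loc[X.index[0], "noise5"] = np.nan
        with pytest.raises(ValueError, match="noise5"):
            cross_validate(X, y, "classification", k=5, seed=0)

    def test_regression_report_includes_trimmed(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() * 2 + rng.normal(0, 0.3, 60)
        report = cross_validate(X, y, "regression", k=5, seed=0,
                                estimator=make_estimator("regression", "random_forest", 0, n_estimators=50))
        assert report.trimmed is not None
        assert report.trimmed["n_retained"] == 60 - 6

    def test_noise_grid_pearson_monotone(self):
        """Planted linear signal: CV Pearson grows as the noise level shrinks."""
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(120, 6)), columns=[f"f{i}" for i in range(6)])
        signal = X[["f0", "f1", "f2", "f3", "f4"]].sum(axis=1).to_numpy()
        pearsons = []
        for sd in (3.0, 1.0, 0.2):
            y = signal + rng.normal(0, sd, 120)
            est = make_estimator("regression", "random_forest", 0, n_estimators=100)
            pearsons.append(
                cross_validate(X, y, "regression", k=5, seed=0, estimator=est).pooled["pearson"]
            )
        assert pearsons[0] < pearsons[1] < pearsons[2]


class TestGreedySelect:
    def test_perfect_feature_found(self, separable_data):
        X, y = separable_data
        trace = greedy_select(X, y, "classification", learner="knn", cv_folds=5, seed=0,
                              patience=2)
        assert "oracle" in trace.best_set
        assert trace.best_metric == pytest.approx(1.0, abs=0.01)

    def test_best_so_far_non_decreasing(self, separable_data):
        X, y = separable_data
        trace = greedy_select(X, y, "classification", learner="knn", cv_folds=5, seed=0,
                              patience=3)
        best_so_far = np.maximum.accumulate([m for _, m in trace.steps])
        assert (np.diff(best_so_far) >= 0).all()
        assert trace.best_metric == pytest.approx(best_so_far[-1])

    def test_matches_stepwise_forward_oracle(self):
        """Independent forward-selection oracle replayed step by step."""
        rng = np.random.default_rng(33)
        n, f = 80, 8
        X = pd.DataFrame(rng.normal(size=(n, f)), columns=[f"f{i}" for i in range(f)])
        y = (X["f1"] + 0.5 * X["f4"] + rng.normal(0, 0.5, n) > 0).astype(float)

        def oracle_cv_auc(cols):
            est = make_estimator("classification", "knn", 0)
            oof = np.empty(n)
            folds = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
            for tr, te in folds.split(X[cols], y):
                est.fit(X[cols].iloc[tr], y[tr])
                oof[te] = est.predict_proba(X[cols].iloc[te])[:, 1]
            return roc_auc_score(y, oof)

        chosen, remaining = [], list(X.columns)
        for _ in range(4):
            scores = [oracle_cv_auc(chosen + [c]) for c in remaining]
            best = remaining[int(np.argmax(scores))]
            chosen.append(best)
            remaining.remove(best)

        trace = greedy_select(X, y, "classification", learner="knn", cv_folds=4, seed=0,
                              patience=100, tolerance=0.0, max_rounds=4)
        assert [f for f, _ in trace.steps] == chosen

    def test_planted_informative_features_recovered(self):
        """3 planted features among 50, recovered in >= 9/10 seeded repeats."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            X = pd.DataFrame(rng.normal(size=(n, 50)), columns=[f"f{i}" for i in range(50)])
            logit = 3.0 * (X["f3"] + X["f17"] + X["f41"]).to_numpy()
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            trace = greedy_select(X, y, "classification", learner="knn", cv_folds=4,
                                  seed=seed, patience=2, max_rounds=8)
            hits += {"f3", "f17", "f41"} <= set(trace.best_set)
        assert hits >= 9

    def test_degenerate_target_rejected(self, separable_data):
        X, _ = separable_data
        with pytest.raises(ValueError, match="degenerate"):
            greedy_select(X, np.ones(len(X)), "classification")
        with pytest.raises(ValueError, match="degenerate"):
            greedy_select(X, np.ones(len(X)), "regression")


class TestTrainModel:
    def test_constant_target_regression(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)), columns=list("abc"))
        bundle = train_model(X, np.full(30, 7.5), "regression", seed=0)
        assert np.allclose(bundle.predict(X), 7.5)

    def test_seeded_refit_reproducible(self, separable_data):
        X, y = separable_data
        p1 = train_model(X, y, "classification", seed=11).predict(X)
        p2 = train_model(X, y, "classification", seed=11).predict(X)
        assert np.array_equal(p1, p2)

    def test_bundle_roundtrips_through_serialization(self, separable_data, tmp_path):
        X, y = separable_data
        bundle = train_model(X, y, "classification", seed=2, selected_features=["oracle", "noise1"])
        path = tmp_path / "model.joblib"
        bundle.save(str(path))
        loaded = ModelBundle.load(str(path))
        assert np.array_equal(bundle.predict(X), loaded.predict(X))
        assert loaded.selected_features == ["oracle", "noise1"]
        assert loaded.config_hash == bundle.config_hash

    def test_predict_missing_features_rejected(self, separable_data):
        X, y = separable_data
        bundle = train_model(X, y, "classification", seed=2)
        with pytest.raises(ValueError, match="missing"):
            bundle.predict(X.drop(columns=["oracle"]))

    @pytest.mark.parametrize("learner", ["random_forest", "extra_trees", "xgb", "knn"])
    def test_learner_family(self, separable_data, learner):
        X, y = separable_data
        est = make_estimator("classification", learner, 0)
        report = cross_validate(X[["oracle"]], y, "classification", k=4, seed=0, estimator=est)
        assert report.pooled["auc"] > 0.95

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="learner"):
            make_estimator("classification", "svm")
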