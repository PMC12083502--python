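"""SVM training, evaluation metrics, aggregate scoring, feature importance."""

import numpy as np
import pandas as pd
import pytest

from dcflow.classify import (
    SplitConfig,
    _stratified_split,
    aggregate_score,
    evaluate,
    hosmer_lemeshow,
    replicate_experiment,
    rf_importance,
    train_imgsvm,
)


def separable_blobs(n_per_class=20, gap=10.0, seed=0, n_features=2):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_class, n_features))
    b = rng.normal(gap, 1.0, (n_per_class, n_features))
    X = np.vstack([a, b])
    y = np.array(["benign"] * n_per_class + ["malignant"] * n_per_class)
    return X, y


class TestTrainImgSVM:
    def test_separable_blobs_classified_perfectly(self):
        X, y = separable_blobs(seed=1)
        Xt, yt = separable_blobs(seed=2)
        model = train_imgsvm(X, y, seed=0)
        assert np.mean(model.predict(Xt) == yt) == 1.0

    def test_uninformative_features_give_majority_rate_cv(self):
        rng = np.random.default_rng(3)
        X = np.zeros((40, 2)) + rng.normal(0, 1e-12, (40, 2))
        y = np.array(["benign"] * 25 + ["malignant"] * 15)
        model = train_imgsvm(X, y, seed=0)
        assert model.selected_params_["cv_accuracy"] == pytest.approx(25 / 40, abs=0.05)

    def test_same_seed_selects_same_hyperparameters(self):
        X, y = separable_blobs(gap=2.0, seed=4)
        a = train_imgsvm(X, y, seed=5).selected_params_
        b = train_imgsvm(X, y, seed=5).selected_params_
        assert a == b

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_imgsvm(X, np.array(["benign"] * 10))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["malignant"] * 10 + ["benign"] * 10)
        prob = np.array([0.9] * 10 + [0.1] * 10)
        m = evaluate(y, prob, y)
        for k in ("accuracy", "sensitivity", "specificity", "auc_roc", "auc_pr"):
            assert m[k] == pytest.approx(1.0)

    def test_all_positive_predictor(self):
        y = np.array(["malignant"] * 10 + ["benign"] * 10)
        pred = np.array(["malignant"] * 20)
        prob = np.full(20, 0.9)
        m = evaluate(pred, prob, y)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == 0.5

    def test_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(9)
        y = rng.choice(["malignant", "benign"], size=20, p=[0.4, 0.6])
        while len(set(y)) < 2:
            y = rng.choice(["malignant", "benign"], size=20)
        prob = np.round(rng.uniform(0, 1, 20), 1)  # coarse grid forces ties
        m = evaluate(np.where(prob > 0.5, "malignant", "benign"), prob, y)
        pos = prob[y == "malignant"]
        neg = prob[y == "benign"]
        conc = 0.0
        for p in pos:
            for n in neg:
                conc += 1.0 if p > n else (0.5 if p == n else 0.0)
        conc /= len(pos) * len(neg)
        assert m["auc_roc"] == pytest.approx(conc, abs=1e-12)

    def test_accuracy_identity_with_sens_spec(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            y = rng.choice(["malignant", "benign"], size=30)
            if len(set(y)) < 2:
                continue
            prob = rng.uniform(0, 1, 30)
            pred = np.where(rng.uniform(0, 1, 30) > 0.5, "malignant", "benign")
            m = evaluate(pred, prob, y)
            P = np.sum(y == "malignant")
            N = 30 - P
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * P + m["specificity"] * N) / 30, abs=1e-12
            )

    def test_single_class_labels_leave_aucs_missing(self):
        y = np.array(["benign"] * 10)
        m = evaluate(y, np.full(10, 0.2), y)
        assert np.isnan(m["auc_roc"]) and np.isnan(m["auc_pr"])


class TestHosmerLemeshow:
    def test_calibrated_null_rejection_rate(self):
        """On labels drawn from externally stated true probabilities the
        p-value is approximately uniform (chi-square on g df, since no
        model was fitted): the 0.05 rejection rate stays in [0.02, 0.09]."""
        rng = np.random.default_rng(11)
        rejections = 0
        runs = 500
        for _ in range(runs):
            p = rng.uniform(0.05, 0.95, 200)
            y = rng.uniform(size=200) < p
            if hosmer_lemeshow(p, y, df_reduction=0) < 0.05:
                rejections += 1
        assert 0.02 <= rejections / runs <= 0.09

    def test_grossly_miscalibrated_probabilities_rejected(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.6, 0.99, 200)
        y = rng.uniform(size=200) < 0.1
        assert hosmer_lemeshow(p, y) < 1e-6


class TestAggregateScore:
    METRICS = ["accuracy", "sensitivity", "specificity", "auc_roc", "auc_pr",
               "calibration_p"]

    def test_dominant_model_scores_60(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame(rng.uniform(0.5, 0.8, (7, 6)),
                             index=[f"m{i}" for i in range(7)], columns=self.METRICS)
        table.loc["m0"] = 0.99
        scores = aggregate_score(table)
        assert scores["m0"] == 60

    def test_identical_rows_share_scores(self):
        table = pd.DataFrame(
            [[0.9] * 6, [0.9] * 6, [0.5] * 6],
            index=["a", "b", "c"], columns=self.METRICS,
        )
        scores = aggregate_score(table)
        assert scores["a"] == scores["b"] == 60
        assert scores["c"] == 54

    def test_seven_distinct_models_score_10_down_to_4(self):
        vals = np.array([[0.1 * (i + 1)] * 6 for i in range(7)])
        table = pd.DataFrame(vals, index=[f"m{i}" for i in range(7)],
                             columns=self.METRICS)
        scores = aggregate_score(table)
        assert sorted(scores // 6) == [4, 5, 6, 7, 8, 9, 10]

    def test_missing_metric_excludes_model(self):
        table = pd.DataFrame(
            [[0.9] * 6, [0.8] * 5 + [np.nan]],
            index=["a", "b"], columns=self.METRICS,
        )
        with pytest.raises(ValueError):
            aggregate_score(table.iloc[:1])
        with pytest.warns(UserWarning, match="excluded"):
            scores = aggregate_score(pd.concat([table, table.iloc[:1]]))
        assert "b" not in scores.index


class TestReplicateExperiment:
    def test_split_sizes_match_protocol(self):
        labels = np.array(["malignant"] * 21 + ["benign"] * 38)
        cfg = SplitConfig()
        rng = np.random.default_rng(0)
        train, test = _stratified_split(labels, cfg, rng)
        assert train.size == 39 and test.size == 20
        assert np.sum(labels[train] == "malignant") == 11
        assert np.sum(labels[test] == "malignant") == 10
        assert len(set(train) & set(test)) == 0

    def test_separable_cohort_perfect_mean_accuracy(self):
        X, y = separable_blobs(n_per_class=30, gap=12.0, seed=14)
        # pad to protocol class counts: 38 benign + 21 malignant
        Xb, yb = separable_blobs(n_per_class=10, gap=12.0, seed=15)
        X = np.vstack([X, Xb[:8]])
        y = np.concatenate([y, ["benign"] * 8])
        cfg = SplitConfig(replications=5, seed=0)
        rep = replicate_experiment(X, y, cfg)
        assert rep.metrics_mean["accuracy"] == 1.0
        assert rep.metrics_sd["accuracy"] == 0.0

    def test_label_permutation_yields_chance_auc(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(59, 12))
        y = np.array(["malignant"] * 21 + ["benign"] * 38)
        rep = replicate_experiment(X, y, SplitConfig(replications=20, seed=1))
        assert abs(rep.metrics_mean["auc_roc"] - 0.5) <= 0.15

    def test_insufficient_cohort_names_shortfall(self):
        X = np.zeros((10, 2))
        y = np.array(["malignant"] * 5 + ["benign"] * 5)
        with pytest.raises(ValueError, match="cohort too small"):
            replicate_experiment(X, y, SplitConfig(replications=1))

    def test_replication_seeds_recorded(self):
        X, y = separable_blobs(n_per_class=30, gap=12.0, seed=17)
        y[:38] = "benign"
        y[38:] = "malignant"
        rep = replicate_experiment(X, y, SplitConfig(
            n_train_pos=8, n_train_neg=20, n_test_pos=8, n_test_neg=8,
            replications=3, seed=100))
        assert rep.replication_seeds == [100, 101, 102]


class TestRFImportance:
    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(60, 12))
        y = np.where(X[:, 0] > 0, "malignant", "benign")
        imp = rf_importance(X, y, seed=0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_signal_feature_ranks_first(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(80, 12))
        y = np.where(X[:, 4] > 0, "malignant", "benign")
        imp = rf_importance(X, y, seed=0)
        assert imp.values.argmax() == 4

    def test_constant_feature_gets_zero_importance(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(60, 4))
        X[:, 2] = 1.0
        y = np.where(X[:, 0] > 0, "malignant", "benign")
        imp = rf_importance(X, y, seed=0)
        assert imp.iloc[2] == 0.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 6))
        y = np.where(X[:, 1] + rng.normal(0, 0.5, 40) > 0, "malignant", "benign")
        a = rf_importance(X, y, seed=7)
        b = rf_importance(X, y, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
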