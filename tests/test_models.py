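import math

import numpy as np
import pytest

from metapath_dti.models import (
    DTIClassifier,
    bedroc,
    evaluate,
    f1_from_confusion,
    importance_stability,
    load_model,
    permutation_importance,
    roc_pr_curves,
    save_model,
)


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise AUC oracle: ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def bedroc_reference(scores, labels, alpha, order_jitter):
    """Independent BEDROC evaluation: explicit sort and plain-loop sums."""
    items = sorted(
        zip(scores, order_jitter, labels), key=lambda t: (-t[0], t[1])
    )
    N = len(items)
    n = sum(lab for _, _, lab in items)
    s = sum(
        math.exp(-alpha * rank / N)
        for rank, (_, _, lab) in enumerate(items, start=1)
        if lab
    )
    rie = s / (n * (1 / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1))
    ra = n / N
    return rie * ra * math.sinh(alpha / 2) / (
        math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
    ) + 1 / (1 - math.exp(alpha * (1 - ra)))


class TestF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(2, 1, 1, 2 / 3), (5, 0, 0, 1.0), (0, 3, 2, 0.0)],
    )
    def test_formula(self, tp, fp, fn, expected):
        assert f1_from_confusion(tp, fp, fn) == pytest.approx(expected)

    def test_degenerate_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert f1_from_confusion(0, 0, 0) == 0.0
        assert any("undefined" in m for m in caplog.messages)

    def test_matches_harmonic_mean_of_precision_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 30, size=3)
            prec, rec = tp / (tp + fp), tp / (tp + fn)
            assert f1_from_confusion(tp, fp, fn) == pytest.approx(
                2 * prec * rec / (prec + rec)
            )


class TestRocPr:
    def test_perfect_ranking(self):
        out = roc_pr_curves([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert out["auc_roc"] == pytest.approx(1.0)
        assert out["auc_pr"] == pytest.approx(1.0)

    def test_inverted_ranking(self):
        out = roc_pr_curves([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert out["auc_roc"] == pytest.approx(0.0)

    def test_worked_example(self):
        # pos 0.9, 0.8 / neg 0.85, 0.1: 3 of 4 pos-neg pairs ranked correctly
        out = roc_pr_curves([0.9, 0.8, 0.85, 0.1], [1, 1, 0, 0])
        assert out["auc_roc"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_mann_whitney_statistic(self, seed):
        """Trapezoid ROC area equals the pairwise win fraction, ties half."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.choice([0.0, 0.2, 0.5, 0.8, 1.0], size=n)  # heavy ties
        out = roc_pr_curves(scores, labels)
        assert out["auc_roc"] == pytest.approx(mann_whitney_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([0.1, 0.2], [1, 1])

    def test_spline_mode_close_to_trapezoid_and_labeled(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        trap = roc_pr_curves(scores, labels, mode="trapezoid")
        spl = roc_pr_curves(scores, labels, mode="spline")
        assert spl["auc_mode"] == "spline"
        assert abs(spl["auc_roc"] - trap["auc_roc"]) < 0.02


class TestBedroc:
    def test_best_case_near_one(self):
        scores = np.concatenate([np.linspace(1, 0.9, 5), np.linspace(0.5, 0, 95)])
        labels = np.array([1] * 5 + [0] * 95)
        value = bedroc(scores, labels, alpha=20.0)
        jitter = np.arange(100)
        assert value == pytest.approx(
            bedroc_reference(scores, labels, 20.0, jitter), abs=1e-12
        )
        assert value > 0.99

    def test_worst_case_near_zero(self):
        scores = np.concatenate([np.linspace(1, 0.9, 95), np.linspace(0.5, 0, 5)])
        labels = np.array([0] * 95 + [1] * 5)
        assert bedroc(scores, labels, alpha=20.0) < 0.01

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        scores = rng.permutation(n) / n  # distinct scores: tie policy moot
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        value = bedroc(scores, labels, alpha=20.0, seed=3)
        ref = bedroc_reference(scores, labels, 20.0, np.zeros(n))
        assert value == pytest.approx(ref, abs=1e-12)

    def test_monotone_in_active_rank(self):
        """Promoting an active to a better rank never decreases BEDROC."""
        rng = np.random.default_rng(2)
        scores = np.sort(rng.random(40))[::-1].copy()
        labels = np.zeros(40, int)
        labels[[5, 17, 30]] = 1
        base = bedroc(scores, labels, alpha=20.0)
        promoted = labels.copy()
        promoted[[5, 17, 30]] = 0
        promoted[[2, 17, 30]] = 1
        assert bedroc(scores, promoted, alpha=20.0) >= base

    def test_small_alpha_approaches_pairwise_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.random(300)
        labels = rng.integers(0, 2, size=300)
        labels[:2] = [0, 1]
        b = bedroc(scores, labels, alpha=1e-3)
        assert abs(b - mann_whitney_auc(scores, labels)) < 0.05

    def test_degenerate_label_sets_rejected(self):
        with pytest.raises(ValueError):
            bedroc([0.1, 0.2], [1, 1], alpha=20.0)
        with pytest.raises(ValueError):
            bedroc([0.1, 0.2], [0, 1], alpha=0.0)


def separable_data(n=60, p=6, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, p))
    X[:, 0] = y * 4.0 + rng.normal(0, 0.1, n)
    return X, y


class TestClassifier:
    def test_degenerate_grid_is_chosen(self):
        X, y = separable_data()
        m = DTIClassifier("rf", ntree=25, mtry_grid=[2], random_state=0).fit(X, y)
        assert m.best_params_ == {"mtry": 2}
        assert 0.0 <= m.oob_error_ <= 1.0

    def test_separable_training_f1_is_one(self):
        X, y = separable_data()
        m = DTIClassifier("rf", ntree=25, random_state=0).fit(X, y)
        report = evaluate(m, X, y)
        assert report.f1 == 1.0

    def test_same_seed_same_hyperparameters(self):
        X, y = separable_data(seed=4)
        a = DTIClassifier("rf", ntree=25, random_state=7).fit(X, y)
        b = DTIClassifier("rf", ntree=25, random_state=7).fit(X, y)
        assert a.best_params_ == b.best_params_
        np.testing.assert_array_equal(a.positive_scores(X), b.positive_scores(X))

    def test_svm_grid_search_and_zscoring(self):
        X, y = separable_data(n=40)
        m = DTIClassifier(
            "svm", c_grid=(1.0, 4.0), lambda_grid=(0.01, 0.1), cv_folds=3,
            random_state=0,
        ).fit(X, y)
        assert set(m.best_params_) == {"C", "lambda"}
        scores = m.positive_scores(X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_class_rejected(self):
        X = np.random.rand(10, 3)
        with pytest.raises(ValueError, match="two classes"):
            DTIClassifier("rf").fit(X, np.zeros(10))

    def test_nan_features_rejected(self):
        X, y = separable_data(n=20)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            DTIClassifier("rf").fit(X, y)

    def test_predict_proba_contract(self):
        X, y = separable_data()
        m = DTIClassifier("rf", ntree=25, random_state=0).fit(X, y)
        proba = m.predict_proba(X)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert m.predict_proba(np.empty((0, X.shape[1]))).shape == (0, 2)
        with pytest.raises(ValueError, match="mismatch"):
            m.predict_proba(X[:, :3])

    def test_round_trips_through_serialization(self, tmp_path):
        X, y = separable_data()
        m = DTIClassifier("rf", ntree=10, random_state=0).fit(X, y)
        save_model(m, tmp_path / "model.joblib")
        again = load_model(tmp_path / "model.joblib")
        np.testing.assert_array_equal(m.positive_scores(X), again.positive_scores(X))


class TestImportance:
    def make_planted(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        X = rng.normal(size=(n, 5))
        X[:, 1] = 1.0          # constant feature
        X[:, 3] = y.astype(float)  # oracle feature
        return X, y

    def test_constant_feature_has_zero_mda_and_oracle_feature_tops(self):
        X, y = self.make_planted()
        m = DTIClassifier("rf", ntree=50, mtry_grid=[2], random_state=0).fit(X, y)
        imp = permutation_importance(m, X, y, n_repeats=3, seed=1)
        assert imp.mda[1] == pytest.approx(0.0, abs=1e-9)
        assert int(np.argmax(imp.mda)) == 3
        assert imp.mdg is not None and int(np.argmax(imp.mdg)) == 3

    def test_plain_mode_agrees_on_oracle_feature(self):
        X, y = self.make_planted(seed=2)
        m = DTIClassifier("rf", ntree=50, mtry_grid=[2], random_state=0).fit(X, y)
        imp = permutation_importance(m, X, y, n_repeats=3, seed=1, use_oob=False)
        assert int(np.argmax(imp.mda)) == 3

    def test_svm_has_no_gini_bookkeeping(self):
        X, y = self.make_planted()
        m = DTIClassifier("svm", c_grid=(1.0,), lambda_grid=(0.1,), cv_folds=3,
                          random_state=0).fit(X, y)
        imp = permutation_importance(m, X, y, n_repeats=2, seed=0)
        assert imp.mdg is None

    def test_stability_experiment_is_deterministic(self):
        X, y = self.make_planted(n=160, seed=3)
        kwargs = dict(
            n_models=2, train_pos=30, train_neg=30, test_pos=10, test_neg=10,
            seed=9, ntree=15, mda_repeats=1,
        )
        a = importance_stability(X, y, **kwargs)
        b = importance_stability(X, y, **kwargs)
        np.testing.assert_array_equal(a["mda_per_model"], b["mda_per_model"])
        np.testing.assert_array_equal(a["f1_per_model"], b["f1_per_model"])
        assert a["f1_min"] <= a["f1_max"] <= 1.0

    def test_stability_oracle_feature_dominates(self):
        X, y = self.make_planted(n=200, seed=4)
        rep = importance_stability(
            X, y, n_models=3, train_pos=40, train_neg=40, test_pos=15, test_neg=15,
            seed=2, ntree=25, mda_repeats=1,
        )
        means = rep["mda_mean"]
        assert int(np.argmax(means)) == 3
        # a no-signal feature varies less than the planted feature's mean
        assert rep["mda_sd"][0] < means[3]

    def test_insufficient_pairs_rejected(self):
        X, y = self.make_planted(n=40)
        with pytest.raises(ValueError, match="not enough"):
            importance_stability(X, y, n_models=1, train_pos=100, train_neg=100,
                                 test_pos=50, test_neg=50)
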