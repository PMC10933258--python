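"""Splitting, tuning, soft voting, and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from gaitpath.classify import (
    ClassifyError,
    GuardedLabels,
    LeakageError,
    MODEL_NAMES,
    ModelBundle,
    _make_folds,
    confusion_counts,
    metrics_report,
    optimize_vote_weights,
    predict_model,
    predict_soft_vote,
    repeated_cv_evaluate,
    stratified_split,
    train_bundle,
    tune_hyperparameters,
)


class TestStratifiedSplit:
    def test_round_half_up_per_class_counts(self):
        ids = [f"s{i}" for i in range(120)]
        labels = ["big"] * 100 + ["small"] * 20
        split = stratified_split(ids, labels, ratio=0.15, seed=0)
        test_labels = [labels[ids.index(i)] for i in split.test_ids]
        assert test_labels.count("big") == 15
        assert test_labels.count("small") == 3

    def test_partition_is_disjoint_and_complete(self):
        ids = [f"s{i}" for i in range(60)]
        labels = (["a"] * 30) + (["b"] * 20) + (["c"] * 10)
        split = stratified_split(ids, labels, ratio=0.2, seed=1)
        assert set(split.train_ids) | set(split.test_ids) == set(ids)
        assert set(split.train_ids) & set(split.test_ids) == set()

    def test_deterministic_by_seed(self):
        ids = [f"s{i}" for i in range(40)]
        labels = ["a"] * 20 + ["b"] * 20
        one = stratified_split(ids, labels, ratio=0.15, seed=5)
        two = stratified_split(ids, labels, ratio=0.15, seed=5)
        assert one.test_ids == two.test_ids

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ClassifyError):
            stratified_split(["a", "b"], ["x", "y"], ratio=0.0)
        with pytest.raises(ClassifyError, match="fewer than 2"):
            stratified_split(["a", "b", "c"], ["x", "x", "lone"], ratio=0.5)


def separable_data(n=40, margin=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b"], n // 2)
    X = pd.DataFrame({
        "f1": rng.normal(scale=0.3, size=n) + margin * (y == "b"),
        "f2": rng.normal(scale=0.3, size=n) - margin * (y == "b"),
    })
    return X, y


PRESET_HP = {name: tune_hyperparameters(name, None, None, preset="paper")
             for name in MODEL_NAMES}


class TestTuning:
    def test_paper_preset_values(self):
        assert PRESET_HP["SVM"]["kernel"] == "linear"
        assert PRESET_HP["SVM"]["C"] == 70.0
        assert PRESET_HP["KNN"] == {"metric": "manhattan", "n_neighbors": 6,
                                    "weights": "uniform", "algorithm": "kd_tree",
                                    "leaf_size": 10}
        assert PRESET_HP["RF"]["n_estimators"] == 6984
        assert PRESET_HP["LREGR"] == {"C": 0.7, "solver": "sag",
                                      "max_iter": 5000}

    def test_budget_one_returns_the_single_sampled_configuration(self):
        from sklearn.model_selection import ParameterSampler
        from gaitpath.classify import default_search_space
        X, y = separable_data()
        space = default_search_space("KNN")
        expected = list(ParameterSampler(space, n_iter=1, random_state=3))[0]
        got = tune_hyperparameters("KNN", X, y, budget=1, seed=3, cv_folds=2)
        assert got == expected

    def test_zero_budget_rejected(self):
        X, y = separable_data()
        with pytest.raises(ClassifyError, match="budget"):
            tune_hyperparameters("KNN", X, y, budget=0)


def small_bundle(seed=0):
    X, y = separable_data(seed=seed)
    hp = {"SVM": {"kernel": "linear", "C": 1.0},
          "RF": {"n_estimators": 30},
          "LREGR": {"C": 1.0, "solver": "lbfgs", "max_iter": 1000},
          "KNN": {"n_neighbors": 3}}
    return train_bundle(X, y, hp, seed=seed), X, y


class TestBundle:
    def test_separable_data_fit_perfectly_by_all_models(self):
        bundle, X, y = small_bundle()
        for name in MODEL_NAMES:
            pred = predict_model(bundle, name, X)
            assert metrics_report(y, pred).macro["balanced_accuracy"] == 1.0

    def test_probability_rows_sum_to_one(self):
        bundle, X, _ = small_bundle()
        for name in MODEL_NAMES:
            proba = bundle.predict_proba(name, X)
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_refit_with_same_seed_reproduces_predictions(self):
        b1, X, _ = small_bundle(seed=4)
        b2, _, _ = small_bundle(seed=4)
        for name in MODEL_NAMES:
            np.testing.assert_array_equal(b1.predict_proba(name, X),
                                          b2.predict_proba(name, X))

    def test_non_finite_features_rejected(self):
        X, y = separable_data()
        X.iloc[0, 0] = np.inf
        with pytest.raises(ClassifyError, match="finite"):
            train_bundle(X, y, {n: {} for n in MODEL_NAMES})

    def test_prediction_invariant_to_column_permutation(self):
        bundle, X, _ = small_bundle()
        shuffled = X[list(X.columns[::-1])]
        for name in (*MODEL_NAMES, "MV"):
            if name == "MV":
                bundle.weights = np.full(4, 0.25)
            np.testing.assert_array_equal(predict_model(bundle, name, X),
                                          predict_model(bundle, name, shuffled))


class _StubModel:
    """Fixed-probability classifier for voting tests."""

    def __init__(self, proba, classes):
        self._proba = np.asarray(proba, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return np.tile(self._proba, (len(X), 1))


def stub_bundle(probas, classes=("a", "b")):
    models = {name: _StubModel(p, classes)
              for name, p in zip(MODEL_NAMES, probas)}
    return ModelBundle(models=models, hyperparameters={},
                       classes_=np.asarray(classes), feature_names=["f"])


class TestSoftVoting:
    def test_one_hot_weights_reduce_to_single_model(self):
        bundle, X, _ = small_bundle()
        bundle.weights = np.array([1.0, 0.0, 0.0, 0.0])
        mv = predict_model(bundle, "MV", X)
        np.testing.assert_array_equal(mv, predict_model(bundle, "SVM", X))

    def test_weighted_mean_of_probabilities(self):
        bundle = stub_bundle([[0.6, 0.4], [0.2, 0.8], [0.5, 0.5], [0.5, 0.5]])
        bundle.weights = np.array([0.5, 0.5, 0.0, 0.0])
        X = pd.DataFrame({"f": [0.0]})
        labels, proba = predict_soft_vote(bundle, X)
        np.testing.assert_allclose(proba[0], [0.4, 0.6])
        assert labels[0] == "b"

    def test_argmax_tie_breaks_to_first_class_label(self):
        bundle = stub_bundle([[0.5, 0.5]] * 4)
        bundle.weights = np.full(4, 0.25)
        labels, _ = predict_soft_vote(bundle, pd.DataFrame({"f": [0.0]}))
        assert labels[0] == "a"

    def test_permuting_models_with_weights_is_invariant(self):
        probas = [[0.9, 0.1], [0.1, 0.9], [0.6, 0.4], [0.3, 0.7]]
        w = np.array([0.4, 0.3, 0.2, 0.1])
        X = pd.DataFrame({"f": [0.0]})
        b1 = stub_bundle(probas)
        b1.weights = w
        perm = [2, 0, 3, 1]
        b2 = stub_bundle([probas[i] for i in perm])
        b2.weights = w[perm]
        np.testing.assert_allclose(predict_soft_vote(b1, X)[1],
                                   predict_soft_vote(b2, X)[1])

    def test_vote_weight_optimization_favors_the_perfect_model(self):
        rng = np.random.default_rng(0)
        y_val = np.repeat(["a", "b"], 20)
        X_val = pd.DataFrame({"f": np.zeros(40)})

        class PerSample(_StubModel):
            def __init__(self, probas, classes):
                self._p = np.asarray(probas)
                self.classes_ = np.asarray(classes)

            def predict_proba(self, X):
                return self._p

        perfect = np.where((y_val == "a")[:, None], [0.95, 0.05], [0.05, 0.95])
        bundle = stub_bundle([[0.5, 0.5]] * 4)
        bundle.models["SVM"] = PerSample(perfect, ["a", "b"])
        for name in ("RF", "LREGR", "KNN"):  # confidently wrong at random
            noise = rng.random(40)[:, None]
            wrong = np.where((y_val == "a")[:, None], [0.1, 0.9], [0.9, 0.1])
            bundle.models[name] = PerSample(0.8 * wrong + 0.2 * noise, ["a", "b"])
        w = optimize_vote_weights(bundle, X_val, y_val, budget=50, seed=1)
        assert w.sum() == pytest.approx(1.0) and (w >= 0).all()
        assert np.argmax(w) == 0  # plurality mass on the perfect model
        bundle.weights = w
        pred, _ = predict_soft_vote(bundle, X_val)
        assert metrics_report(y_val, pred).macro["balanced_accuracy"] == 1.0

    def test_budget_one_without_vertices_returns_that_draw(self):
        bundle = stub_bundle([[0.6, 0.4]] * 4)
        y_val = np.array(["a", "b"])
        X_val = pd.DataFrame({"f": [0.0, 0.0]})
        w = optimize_vote_weights(bundle, X_val, y_val, budget=1, seed=9,
                                  include_vertices=False)
        expected = np.random.default_rng(9).dirichlet(np.ones(4))
        np.testing.assert_allclose(w, expected)


class TestMetrics:
    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        rep = metrics_report(y, y)
        assert all(v == 1.0 for v in rep.macro.values())
        for counts in rep.confusion.values():
            assert counts["FP"] == counts["FN"] == 0

    def test_hand_counted_confusion(self):
        tp, tn, fp, fn = confusion_counts(
            ["A", "A", "B", "B"], ["A", "B", "B", "B"], "A")
        assert (tp, tn, fp, fn) == (1, 2, 0, 1)

    def test_swapping_true_and_predicted_swaps_fp_fn(self):
        y1 = ["A", "A", "B", "B", "A"]
        y2 = ["A", "B", "B", "A", "A"]
        tp1, tn1, fp1, fn1 = confusion_counts(y1, y2, "A")
        tp2, tn2, fp2, fn2 = confusion_counts(y2, y1, "A")
        assert (tp1, tn1) == (tp2, tn2)
        assert (fp1, fn1) == (fn2, fp2)

    def test_unknown_class_rejected(self):
        with pytest.raises(ClassifyError, match="unknown class"):
            confusion_counts(["a"], ["a"], "zz")

    def test_balanced_accuracy_of_coin_flip_counts(self):
        rep = metrics_report(["p", "p", "n", "n"], ["p", "n", "p", "n"])
        assert rep.per_class["p"]["balanced_accuracy"] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_labelings(self):
        """The report formulas agree with a from-scratch confusion-count
        implementation on 1000 random multiclass labelings."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(2, 30)
            k = rng.integers(2, 5)
            classes = [f"c{i}" for i in range(k)]
            y_true = rng.choice(classes, size=n)
            y_pred = rng.choice(classes, size=n)
            rep = metrics_report(y_true, y_pred)
            seen = sorted(set(y_true) | set(y_pred))
            accum = {m: [] for m in ("balanced_accuracy", "recall",
                                     "precision", "f1")}
            for cls in seen:
                tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
                tn = sum(t != cls and p != cls for t, p in zip(y_true, y_pred))
                fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
                fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
                rec = tp / (tp + fn) if tp + fn else 0.0
                spec = tn / (tn + fp) if tn + fp else 0.0
                prec = tp / (tp + fp) if tp + fp else 0.0
                f1 = (2 * prec * rec / (prec + rec)) if prec + rec else 0.0
                expected = {"balanced_accuracy": 0.5 * (rec + spec),
                            "recall": rec, "precision": prec, "f1": f1}
                for m, v in expected.items():
                    assert abs(rep.per_class[cls][m] - v) < 1e-12
                    accum[m].append(v)
            for m in accum:
                assert abs(rep.macro[m] - np.mean(accum[m])) < 1e-12

    def test_random_classifier_scores_near_half(self):
        """Uniformly random predictions give macro balanced accuracy about
        0.5 on the reference class structure."""
        import gaitpath as gp
        labels = np.repeat(list(gp.DEFAULT_CLASS_COUNTS),
                           list(gp.DEFAULT_CLASS_COUNTS.values()))
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pred = rng.choice(sorted(set(labels)), size=len(labels))
            scores.append(metrics_report(labels, pred).macro["balanced_accuracy"])
        assert abs(np.mean(scores) - 0.5) < 0.05


class TestRepeatedCv:
    HP = {"SVM": {"kernel": "linear", "C": 1.0},
          "RF": {"n_estimators": 20},
          "LREGR": {"C": 1.0, "solver": "lbfgs", "max_iter": 500},
          "KNN": {"n_neighbors": 3}}

    def test_loocv_fold_count_equals_n(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        folds = _make_folds(y, "leave_one_out", n_folds=0, seed=0)
        assert len(folds) == 10
        assert all(len(test) == 1 for _, test in folds)

    def test_loocv_above_cap_advises_kfold(self):
        X, y = separable_data(n=40)
        with pytest.raises(ClassifyError, match="stratified_kfold"):
            repeated_cv_evaluate(X, y, self.HP, scheme="leave_one_out",
                                 loocv_cap=10)

    def test_learning_curve_traces_grow_with_fraction(self):
        import matplotlib
        matplotlib.use("Agg")
        from gaitpath.classify import learning_curve_data
        from gaitpath.plotting import plot_learning_curve
        X, y = separable_data(n=60, seed=3)
        lc = learning_curve_data(X, y, self.HP, fractions=(0.5, 1.0),
                                 n_folds=2, seed=0)
        assert list(lc["n_samples"]) == sorted(lc["n_samples"])
        assert lc["score_mean"].between(0, 1).all()
        assert plot_learning_curve(lc) is not None

    def test_identical_seeds_give_identical_distributions(self):
        X, y = separable_data(n=30, seed=2)
        a = repeated_cv_evaluate(X, y, self.HP, repeats=2, n_folds=3, seed=7)
        b = repeated_cv_evaluate(X, y, self.HP, repeats=2, n_folds=3, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["model"]) == {*MODEL_NAMES, "MV"}


class TestGuardedLabels:
    def test_reads_raise_until_scoring(self):
        guard = GuardedLabels(["a", "b"])
        with pytest.raises(LeakageError):
            _ = guard.values
        assert guard.accesses == 0
        np.testing.assert_array_equal(guard.for_scoring(), ["a", "b"])
        assert guard.accesses == 1
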