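"""Classifier training, soft voting, and evaluation metrics.

Four probabilistic base classifiers — a support vector machine (with
cross-validated probability calibration), a random forest, one-vs-rest
logistic regression, and k-nearest neighbours — are tuned by randomized
search (grid search for the logistic regression, which needs exhaustive
search for stable convergence), trained on the stratified 85 % training
partition, and combined by weighted soft voting: the ensemble probability
is the weight-averaged probability of the members, with nonnegative
weights summing to one chosen by randomized search on a validation split.

Evaluation follows the one-vs-rest confusion-count formulas:

* balanced accuracy = (TP/(TP+FN) + TN/(TN+FP)) / 2
* recall            = TP/(TP+FN)
* precision         = TP/(TP+FP)
* F1                = 2 * precision * recall / (precision + recall)

computed per class and macro-averaged (unweighted mean over classes);
ratios with a zero denominator are reported as 0 and flagged.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, ParameterSampler, StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

MODEL_NAMES = ("SVM", "RF", "LREGR", "KNN")

#: Loss-change stopping tolerance for the iterative learners.
STOP_TOL = 1e-4


class ClassifyError(ValueError):
    pass


class LeakageError(RuntimeError):
    """Test labels were read outside of scoring."""


class GuardedLabels:
    """Access guard around held-out labels.

    Any read of ``values`` before :meth:`for_scoring` is called raises
    :class:`LeakageError`; the pipeline's fitting stages therefore cannot
    consume test labels even by accident.
    """

    def __init__(self, labels: Sequence[str]):
        self._labels = np.asarray(labels)
        self.accesses = 0

    @property
    def values(self) -> np.ndarray:
        raise LeakageError("test labels may only be read through for_scoring()")

    def __len__(self) -> int:
        return len(self._labels)

    def for_scoring(self) -> np.ndarray:
        """Reveal the labels for metric computation (logged)."""
        self.accesses += 1
        return self._labels.copy()


# ---------------------------------------------------------------------------
# splitting

@dataclasses.dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    ratio: float
    seed: int


def stratified_split(ids: Sequence[str], labels: Sequence[str],
                     ratio: float = 0.15, seed: int = 0) -> SplitResult:
    """Per-class test sampling without replacement.

    The test count per class is round-half-up(ratio * class size), at
    least 1; deterministic by seed.
    """
    if not (0 < ratio < 1):
        raise ClassifyError("test ratio must lie in (0, 1)")
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in sorted(set(labels)):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise ClassifyError(f"class {cls!r} has fewer than 2 subjects")
        n_test = max(1, int(np.floor(ratio * members.size + 0.5)))
        chosen = rng.choice(members, size=n_test, replace=False)
        test_idx.extend(chosen.tolist())
    test_set = set(test_idx)
    return SplitResult(
        train_ids=[str(ids[i]) for i in range(len(ids)) if i not in test_set],
        test_ids=[str(ids[i]) for i in sorted(test_idx)],
        ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# hyperparameter search

def default_search_space(name: str) -> dict:
    """Search ranges per algorithm (randomized; grid for LREGR)."""
    spaces = {
        "SVM": {
            "kernel": ["linear", "rbf"],
            "gamma": ["scale", 0.01, 0.1, 1.0],
            "C": [0.1, 1.0, 10.0, 70.0, 100.0],
        },
        "RF": {
            "n_estimators": [100, 300, 600],
            "criterion": ["gini", "entropy"],
            "min_samples_split": [2, 4, 8],
            "min_samples_leaf": [1, 2, 4],
            "max_depth": [10, 40, None],
            "max_features": ["sqrt", "log2"],
            "bootstrap": [True, False],
        },
        "LREGR": {
            "C": [0.1, 0.7, 1.0, 10.0],
            "solver": ["sag", "lbfgs"],
            "max_iter": [5000],
        },
        "KNN": {
            "metric": ["manhattan", "euclidean"],
            "weights": ["uniform", "distance"],
            "algorithm": ["kd_tree", "ball_tree"],
            "leaf_size": [10, 30],
            "n_neighbors": [3, 4, 5, 6, 8, 10],
        },
    }
    if name not in spaces:
        raise ClassifyError(f"unknown algorithm {name!r}")
    return spaces[name]


#: Hyperparameters reported for the original clinical cohort; available as
#: ``preset="paper"`` (the forest size in particular is data-specific).
PAPER_PRESET: dict[str, dict] = {
    "SVM": {"kernel": "linear", "C": 70.0, "gamma": "scale"},
    "RF": {"n_estimators": 6984, "criterion": "gini", "min_samples_split": 2,
           "min_samples_leaf": 1, "max_depth": 40, "max_features": "sqrt",
           "bootstrap": True},
    "LREGR": {"C": 0.7, "solver": "sag", "max_iter": 5000},
    "KNN": {"metric": "manhattan", "n_neighbors": 6, "weights": "uniform",
            "algorithm": "kd_tree", "leaf_size": 10},
}


def build_estimator(name: str, params: dict, seed: int = 0):
    """Instantiate one base classifier with class-probability output."""
    if name == "SVM":
        svc = SVC(tol=STOP_TOL, random_state=seed, **params)
        # cross-validated sigmoid calibration supplies predict_proba
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "LREGR":
        return OneVsRestClassifier(
            LogisticRegression(tol=STOP_TOL, random_state=seed, **params))
    if name == "KNN":
        return KNeighborsClassifier(**params)
    raise ClassifyError(f"unknown algorithm {name!r}")


def tune_hyperparameters(name: str, X: pd.DataFrame, y, budget: int = 10,
                         seed: int = 0, cv_folds: int = 3,
                         space: dict | None = None,
                         preset: str | None = None) -> dict:
    """Pick hyperparameters by CV balanced accuracy on training data.

    Randomized search (*budget* draws) for SVM/RF/KNN; exhaustive grid for
    LREGR. ``preset="paper"`` bypasses the search and returns the
    hyperparameters tuned on the original clinical cohort.
    """
    if preset == "paper":
        return dict(PAPER_PRESET[name])
    if budget < 1:
        raise ClassifyError("search budget must be >= 1")
    space = space or default_search_space(name)
    if name == "LREGR":
        candidates = list(ParameterGrid(space))
    else:
        candidates = list(ParameterSampler(space, n_iter=min(budget, _space_size(space)),
                                           random_state=seed))
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_score, best_params = -np.inf, candidates[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for params in candidates:
            est = build_estimator(name, params, seed=seed)
            score = cross_val_score(est, X.to_numpy(), y, cv=cv,
                                    scoring="balanced_accuracy").mean()
            if score > best_score:
                best_score, best_params = score, params
    return dict(best_params)


def _space_size(space: dict) -> int:
    n = 1
    for v in space.values():
        n *= len(v)
    return n


# ---------------------------------------------------------------------------
# model bundle and soft voting

@dataclasses.dataclass
class ModelBundle:
    """Four fitted probabilistic classifiers plus soft-voting weights."""

    models: dict  # name -> fitted estimator
    hyperparameters: dict[str, dict]
    classes_: np.ndarray
    feature_names: list[str]
    weights: np.ndarray | None = None  # 4 nonnegative reals summing to 1

    def predict_proba(self, name: str, X: pd.DataFrame) -> np.ndarray:
        """Class probabilities of one member, columns in ``classes_`` order."""
        self._check_features(X)
        model = self.models[name]
        proba = model.predict_proba(X[self.feature_names].to_numpy())
        order = [list(model.classes_).index(c) for c in self.classes_]
        return proba[:, order]

    def _check_features(self, X: pd.DataFrame) -> None:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ClassifyError(f"feature-set mismatch, missing: {missing[:5]}")


def train_bundle(X: pd.DataFrame, y, hyperparameters: dict[str, dict],
                 seed: int = 0) -> ModelBundle:
    """Fit the four base classifiers on selected, scaled training features."""
    if not np.all(np.isfinite(X.to_numpy())):
        raise ClassifyError("non-finite feature values in training table")
    y = np.asarray(y)
    models = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in MODEL_NAMES:
            est = build_estimator(name, hyperparameters[name], seed=seed)
            est.fit(X.to_numpy(), y)
            models[name] = est
    return ModelBundle(
        models=models,
        hyperparameters={k: dict(v) for k, v in hyperparameters.items()},
        classes_=np.array(sorted(set(y))),
        feature_names=list(X.columns),
    )


def optimize_vote_weights(bundle: ModelBundle, X_val: pd.DataFrame, y_val,
                          budget: int = 100, seed: int = 0,
                          include_vertices: bool = True) -> np.ndarray:
    """Randomized search for soft-voting weights on the 4-simplex.

    Candidates are *budget* Dirichlet draws plus, by default, the four
    vertices (single-model votes) and the barycenter; returns the argmax
    of validation macro balanced accuracy (first maximum on ties).
    """
    y_val = np.asarray(y_val)
    rng = np.random.default_rng(seed)
    candidates: list[np.ndarray] = []
    if include_vertices:
        candidates += [np.eye(4)[i] for i in range(4)] + [np.full(4, 0.25)]
    if budget > 0:
        candidates += list(rng.dirichlet(np.ones(4), size=budget))
    if not candidates:
        raise ClassifyError("empty candidate set: budget must be >= 1")
    probas = {name: bundle.predict_proba(name, X_val) for name in MODEL_NAMES}
    best_score, best_w = -np.inf, candidates[0]
    for w in candidates:
        mixed = sum(wi * probas[name] for wi, name in zip(w, MODEL_NAMES))
        pred = _argmax_labels(mixed, bundle.classes_)
        score = metrics_report(y_val, pred).macro["balanced_accuracy"]
        if score > best_score:
            best_score, best_w = score, w
    return np.asarray(best_w, dtype=float)


def _argmax_labels(proba: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # classes are sorted, so argmax's first-maximum rule breaks ties
    # toward the lexicographically first label
    return classes[np.argmax(proba, axis=1)]


def predict_soft_vote(bundle: ModelBundle, X: pd.DataFrame
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted soft vote: P = sum_m w_m P_m; returns (labels, probabilities)."""
    if bundle.weights is None:
        raise ClassifyError("bundle has no voting weights; run optimize_vote_weights")
    mixed = sum(w * bundle.predict_proba(name, X)
                for w, name in zip(bundle.weights, MODEL_NAMES))
    return _argmax_labels(mixed, bundle.classes_), mixed


def predict_model(bundle: ModelBundle, name: str, X: pd.DataFrame) -> np.ndarray:
    """Hard predictions of one member (or ``"MV"`` for the ensemble)."""
    if name == "MV":
        return predict_soft_vote(bundle, X)[0]
    return _argmax_labels(bundle.predict_proba(name, X), bundle.classes_)


# ---------------------------------------------------------------------------
# metrics

@dataclasses.dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    confusion: dict[str, dict[str, int]]  # class -> {TP, TN, FP, FN}
    undefined: list[tuple[str, str]]      # (class, metric) with 0 denominator

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_class).T
        df.loc["macro"] = self.macro
        return df


def confusion_counts(y_true, y_pred, cls) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for one class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ClassifyError("label lists differ in length")
    if cls not in set(y_true) | set(y_pred):
        raise ClassifyError(f"unknown class {cls!r}")
    t = y_true == cls
    p = y_pred == cls
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    return tp, tn, fp, fn


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def metrics_report(y_true, y_pred) -> MetricsReport:
    """Per-class one-vs-rest metrics and their unweighted macro averages."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ClassifyError("empty label lists")
    classes = sorted(set(y_true) | set(y_pred))
    per_class: dict[str, dict[str, float]] = {}
    confusion: dict[str, dict[str, int]] = {}
    undefined: list[tuple[str, str]] = []
    for cls in classes:
        tp, tn, fp, fn = confusion_counts(y_true, y_pred, cls)
        recall, u1 = _safe_div(tp, tp + fn)
        specificity, u2 = _safe_div(tn, tn + fp)
        precision, u3 = _safe_div(tp, tp + fp)
        f1, u4 = _safe_div(2 * precision * recall, precision + recall)
        per_class[cls] = {
            "balanced_accuracy": 0.5 * (recall + specificity),
            "recall": recall,
            "precision": precision,
            "f1": f1,
        }
        confusion[cls] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
        for flag, metric in zip((u1, u2, u3, u4),
                                ("recall", "specificity", "precision", "f1")):
            if flag:
                undefined.append((cls, metric))
    macro = {m: float(np.mean([per_class[c][m] for c in classes]))
             for m in ("balanced_accuracy", "recall", "precision", "f1")}
    return MetricsReport(per_class=per_class, macro=macro,
                         confusion=confusion, undefined=undefined)


# ---------------------------------------------------------------------------
# repeated cross-validation

def repeated_cv_evaluate(X: pd.DataFrame, y, hyperparameters: dict[str, dict],
                         repeats: int = 3, scheme: str = "stratified_kfold",
                         n_folds: int = 5, seed: int = 0,
                         loocv_cap: int = 150) -> pd.DataFrame:
    """Repeated cross-validation of the soft-voting pipeline.

    For each repeat (fresh seeds) the scheme's folds are trained and
    scored; returns a tidy frame with one row per (repeat, model) carrying
    the four macro metrics. ``scheme="leave_one_out"`` errors above
    *loocv_cap* samples, advising k-fold instead.
    """
    y = np.asarray(y)
    n = len(y)
    if scheme == "leave_one_out" and n > loocv_cap:
        raise ClassifyError(
            f"leave-one-out with n={n} exceeds the cap ({loocv_cap}); "
            "use scheme='stratified_kfold'")
    rows = []
    for rep in range(repeats):
        rep_seed = seed + rep
        folds = _make_folds(y, scheme, n_folds, rep_seed)
        y_pred: dict[str, np.ndarray] = {m: np.empty(n, dtype=object)
                                         for m in (*MODEL_NAMES, "MV")}
        for train_idx, test_idx in folds:
            bundle = train_bundle(X.iloc[train_idx], y[train_idx],
                                  hyperparameters, seed=rep_seed)
            bundle.weights = np.full(4, 0.25)  # uniform vote inside CV
            for name in (*MODEL_NAMES, "MV"):
                y_pred[name][test_idx] = predict_model(bundle, name, X.iloc[test_idx])
        for name in (*MODEL_NAMES, "MV"):
            macro = metrics_report(y, y_pred[name].astype(str)).macro
            rows.append({"repeat": rep, "model": name, **macro})
    return pd.DataFrame(rows)


def _make_folds(y: np.ndarray, scheme: str, n_folds: int, seed: int):
    if scheme == "leave_one_out":
        return [(np.delete(np.arange(len(y)), i), np.array([i]))
                for i in range(len(y))]
    if scheme != "stratified_kfold":
        raise ClassifyError(f"unknown CV scheme {scheme!r}")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def learning_curve_data(X: pd.DataFrame, y, hyperparameters: dict[str, dict],
                        fractions=(0.4, 0.6, 0.8, 1.0), n_folds: int = 3,
                        seed: int = 0) -> pd.DataFrame:
    """Score-vs-n-samples traces for learning-curve plots."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        idx = _stratified_subsample(y, frac, rng)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = []
        for train_i, test_i in cv.split(np.zeros(len(idx)), y[idx]):
            tr, te = idx[train_i], idx[test_i]
            bundle = train_bundle(X.iloc[tr], y[tr], hyperparameters, seed=seed)
            bundle.weights = np.full(4, 0.25)
            pred = predict_model(bundle, "MV", X.iloc[te])
            scores.append(metrics_report(y[te], pred).macro["balanced_accuracy"])
        rows.append({"n_samples": len(idx), "fraction": frac,
                     "score_mean": float(np.mean(scores)),
                     "score_std": float(np.std(scores))})
    return pd.DataFrame(rows)


def _stratified_subsample(y: np.ndarray, frac: float, rng) -> np.ndarray:
    keep = []
    for cls in sorted(set(y)):
        members = np.flatnonzero(y == cls)
        n_keep = max(2, int(round(frac * members.size)))
        keep.extend(rng.choice(members, size=min(n_keep, members.size),
                               replace=False).tolist())
    return np.array(sorted(keep))
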