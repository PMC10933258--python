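"""Feature selection: RFE with cross-validation, forest importances, and
their intersection.

Two selectors run independently on the scaled training features:

* recursive feature elimination with a linear-margin (linear SVM)
  estimator, dropping one feature per step — the one with the smallest sum
  of squared one-vs-rest coefficients — and keeping the subset size that
  maximizes mean cross-validated balanced accuracy (ties toward the
  smaller subset);
* a random forest fitted on all features, keeping features whose
  impurity-decrease importance reaches a threshold (default: the mean
  importance).

The final subset is the intersection of the two; an empty intersection
emits a warning and can fall back to the union.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC


class SelectionError(ValueError):
    pass


@dataclasses.dataclass
class SelectionResult:
    rfe_subset: list[str]
    rfe_score_trace: dict[int, float]        # subset size -> mean CV score
    importance_subset: list[str]
    importances: dict[str, float]
    final_subset: list[str]
    provenance: dict


def _check_inputs(X: pd.DataFrame, y: np.ndarray, cv_folds: int) -> None:
    if X.isna().any().any():
        raise SelectionError("feature table contains missing values; impute first")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SelectionError("need at least 2 classes for selection")
    if counts.min() < cv_folds:
        raise SelectionError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} subjects "
            f"< {cv_folds} CV folds")


def rfe_cv_select(X: pd.DataFrame, y, cv_folds: int = 5, seed: int = 0,
                  step: int = 1) -> tuple[list[str], dict[int, float]]:
    """RFE-CV with a linear SVM estimator; returns (subset, score trace).

    sklearn's RFE ranks multiclass coefficients by their squared sum across
    the one-vs-rest decision functions, which is exactly the aggregation
    used here.
    """
    y = np.asarray(y)
    _check_inputs(X, y, cv_folds)
    estimator = LinearSVC(C=1.0, tol=1e-4, max_iter=10000, random_state=seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        if X.shape[1] == 1:  # nothing to eliminate
            from sklearn.model_selection import cross_val_score
            score = cross_val_score(estimator, X.to_numpy(), y, cv=cv,
                                    scoring="balanced_accuracy").mean()
            return list(X.columns), {1: float(score)}
        rfecv = RFECV(estimator, step=step, cv=cv, scoring="balanced_accuracy",
                      min_features_to_select=1, n_jobs=None)
        rfecv.fit(X.to_numpy(), y)
    scores = rfecv.cv_results_["mean_test_score"]
    sizes = _rfe_subset_sizes(X.shape[1], step)
    trace = {int(n): float(s) for n, s in zip(sizes, scores)}
    # RFECV's argmax over sizes (ascending) takes the first maximum, i.e.
    # ties break toward the smaller subset.
    subset = [c for c, keep in zip(X.columns, rfecv.support_) if keep]
    return subset, trace


def _rfe_subset_sizes(n_features: int, step: int) -> list[int]:
    """Subset sizes scored by RFECV, smallest first (matches cv_results_)."""
    sizes = [n_features]
    while sizes[-1] > 1:
        sizes.append(max(1, sizes[-1] - step))
    return sizes[::-1]


def importance_select(X: pd.DataFrame, y, n_trees: int = 500, seed: int = 0,
                      threshold_rule: str = "mean"
                      ) -> tuple[list[str], dict[str, float]]:
    """Keep features whose forest importance reaches the threshold.

    ``threshold_rule`` is ``"mean"`` (default), ``"median"``, or a float.
    """
    y = np.asarray(y)
    _check_inputs(X, y, cv_folds=2)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X.to_numpy(), y)
    imp = forest.feature_importances_
    if threshold_rule == "mean":
        threshold = float(imp.mean())
    elif threshold_rule == "median":
        threshold = float(np.median(imp))
    else:
        threshold = float(threshold_rule)
    subset = [c for c, v in zip(X.columns, imp) if v >= threshold]
    importances = {c: float(v) for c, v in zip(X.columns, imp)}
    return subset, importances


def intersect_subsets(a: list[str], b: list[str],
                      union_fallback: bool = True) -> list[str]:
    """Intersection in canonical (first-argument) order.

    An empty intersection emits a warning; with *union_fallback* the union
    is returned instead so the pipeline can proceed.
    """
    bset = set(b)
    inter = [f for f in a if f in bset]
    if inter:
        return inter
    warnings.warn("feature-subset intersection is empty", stacklevel=2)
    if union_fallback:
        return list(a) + [f for f in b if f not in set(a)]
    return []


def select_features(X: pd.DataFrame, y, cv_folds: int = 5, seed: int = 0,
                    n_trees: int = 500, threshold_rule: str = "mean",
                    rfe_step: int = 1, union_fallback: bool = True
                    ) -> SelectionResult:
    """Run both selectors and intersect their subsets."""
    rfe_subset, trace = rfe_cv_select(X, y, cv_folds=cv_folds, seed=seed, step=rfe_step)
    imp_subset, importances = importance_select(
        X, y, n_trees=n_trees, seed=seed, threshold_rule=threshold_rule)
    final = intersect_subsets(rfe_subset, imp_subset, union_fallback=union_fallback)
    return SelectionResult(
        rfe_subset=rfe_subset,
        rfe_score_trace=trace,
        importance_subset=imp_subset,
        importances=importances,
        final_subset=final,
        provenance={"seed": seed, "cv_folds": cv_folds, "n_trees": n_trees,
                    "threshold_rule": threshold_rule, "rfe_step": rfe_step},
    )
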