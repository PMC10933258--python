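"""Top-level modelling interface: fit the whole pipeline, get a results object.

:class:`GaitConditionModel` holds a cohort plus a :class:`RunConfig`;
:meth:`~GaitConditionModel.fit` executes the full workflow — imputation,
normative reference, derived series, the 374-feature extraction, min-max
scaling, RFE+forest feature selection, the stratified 0.85/0.15 split,
hyperparameter tuning, training of the four base classifiers, soft-vote
weight optimization, and held-out evaluation — and returns a
:class:`GaitConditionResults` carrying the fitted bundle, the selected
features, per-class and macro metrics, and a ``summary()`` table.
Explanations hang off the results object.

Two modes govern information flow:

* ``leakage_safe`` (default): the normative reference, imputation medians,
  scaler and feature selection are all fitted on the training partition
  only; the test partition is imputed pooled (no labels) and its labels
  are wrapped in an access guard that only the scoring step may open.
* ``paper_mode``: feature engineering and selection run on the whole
  cohort before the split, mirroring the original retrospective study's
  stated order (which is leakage-prone; shipped for comparability).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, derive, explain, features, preprocess, select
from .angles import PATHOLOGICAL_CONDITIONS
from .classify import GuardedLabels, ModelBundle
from .io import GaitCohort


@dataclasses.dataclass
class RunConfig:
    """All pipeline settings and seeds; every stochastic stage is seeded."""

    mode: str = "leakage_safe"            # or "paper_mode"
    test_ratio: float = 0.15
    split_seed: int = 0
    selection_seed: int = 0
    tuning_seed: int = 0
    model_seed: int = 0
    voting_seed: int = 0
    lime_seed: int = 0
    selection_cv_folds: int = 5
    selection_trees: int = 500
    importance_threshold: str | float = "mean"
    rfe_step: int = 1
    tuning_budget: int = 10
    tuning_cv_folds: int = 3
    tuning_preset: str | None = None      # "paper" bypasses the search
    voting_budget: int = 100
    validation_ratio: float = 0.15        # of train, for vote weights
    log_features: bool = False
    lime_samples: int = 1000
    lime_subjects: int = 20
    lime_top_k: int = 5

    def __post_init__(self):
        if self.mode not in ("leakage_safe", "paper_mode"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class GaitConditionModel:
    """Foot-condition classification model over a gait cohort.

    Parameters
    ----------
    cohort
        A :class:`~gaitpath.io.GaitCohort`; missing grid values allowed
        (median-imputed during fit).
    config
        Pipeline settings; defaults reproduce the study workflow in
        leakage-safe form.
    """

    def __init__(self, cohort: GaitCohort, config: RunConfig | None = None):
        self.cohort = cohort
        self.config = config or RunConfig()

    @classmethod
    def from_csv(cls, path: str | Path, config: RunConfig | None = None
                 ) -> "GaitConditionModel":
        from .io import read_cohort
        return cls(read_cohort(path), config=config)

    def fit(self) -> "GaitConditionResults":
        cfg = self.config
        ids = [s.subject_id for s in self.cohort.subjects]
        labels = self.cohort.labels()

        split = classify.stratified_split(ids, labels, ratio=cfg.test_ratio,
                                          seed=cfg.split_seed)
        if cfg.mode == "leakage_safe":
            train_tab, test_tab, scaler, selection, normative = \
                self._engineer_leakage_safe(split)
        else:
            train_tab, test_tab, scaler, selection, normative = \
                self._engineer_paper_mode(split)

        feats = selection.final_subset
        X_train, y_train = train_tab[feats], train_tab["condition"].to_numpy()
        X_test = test_tab[feats]
        guard = GuardedLabels(test_tab["condition"].to_numpy())

        # inner split of the training partition for vote-weight validation
        inner = classify.stratified_split(
            list(X_train.index), y_train, ratio=cfg.validation_ratio,
            seed=cfg.split_seed + 1)
        fit_ids, val_ids = inner.train_ids, inner.test_ids
        X_fit, y_fit = X_train.loc[fit_ids], train_tab.loc[fit_ids, "condition"].to_numpy()
        X_val, y_val = X_train.loc[val_ids], train_tab.loc[val_ids, "condition"].to_numpy()

        hyper = {name: classify.tune_hyperparameters(
            name, X_fit, y_fit, budget=cfg.tuning_budget, seed=cfg.tuning_seed,
            cv_folds=cfg.tuning_cv_folds, preset=cfg.tuning_preset)
            for name in classify.MODEL_NAMES}
        bundle = classify.train_bundle(X_fit, y_fit, hyper, seed=cfg.model_seed)
        bundle.weights = classify.optimize_vote_weights(
            bundle, X_val, y_val, budget=cfg.voting_budget, seed=cfg.voting_seed)

        y_test = guard.for_scoring()
        reports = {}
        for name in (*classify.MODEL_NAMES, "MV"):
            pred = classify.predict_model(bundle, name, X_test)
            reports[name] = classify.metrics_report(y_test, pred)

        return GaitConditionResults(
            model=self, split=split, selection=selection, scaler=scaler,
            normative=normative, bundle=bundle, metrics=reports,
            train_table=train_tab, test_table=test_tab, label_guard=guard,
            config_hash=self.config.hash())

    # -- feature engineering under the two modes ---------------------------

    def _engineer_leakage_safe(self, split):
        cfg = self.config
        train = self.cohort.subset(split.train_ids)
        test = self.cohort.subset(split.test_ids)
        imputer = preprocess.fit_imputer(train)
        train = preprocess.apply_imputer(train, imputer, mode="class_conditional")
        test = preprocess.apply_imputer(test, imputer, mode="pooled")
        normative = derive.compute_normative(train)
        train_tab = features.extract_cohort_features(train, normative)
        test_tab = features.extract_cohort_features(test, normative)
        train_tab = preprocess.log_transform(train_tab, cfg.log_features)
        test_tab = preprocess.log_transform(test_tab, cfg.log_features)
        scaler = preprocess.fit_scaler(train_tab)
        train_scaled = preprocess.apply_scaler(train_tab, scaler)
        test_scaled = preprocess.apply_scaler(test_tab, scaler)
        selection = select.select_features(
            train_scaled.drop(columns="condition"),
            train_scaled["condition"].to_numpy(),
            cv_folds=cfg.selection_cv_folds, seed=cfg.selection_seed,
            n_trees=cfg.selection_trees, threshold_rule=cfg.importance_threshold,
            rfe_step=cfg.rfe_step)
        return train_scaled, test_scaled, scaler, selection, normative

    def _engineer_paper_mode(self, split):
        cfg = self.config
        whole = self.cohort.copy()
        imputer = preprocess.fit_imputer(whole)
        whole = preprocess.apply_imputer(whole, imputer, mode="class_conditional")
        normative = derive.compute_normative(whole)
        table = features.extract_cohort_features(whole, normative)
        table = preprocess.log_transform(table, cfg.log_features)
        scaler = preprocess.fit_scaler(table)
        scaled = preprocess.apply_scaler(table, scaler)
        selection = select.select_features(
            scaled.drop(columns="condition"), scaled["condition"].to_numpy(),
            cv_folds=cfg.selection_cv_folds, seed=cfg.selection_seed,
            n_trees=cfg.selection_trees, threshold_rule=cfg.importance_threshold,
            rfe_step=cfg.rfe_step)
        return scaled.loc[split.train_ids], scaled.loc[split.test_ids], \
            scaler, selection, normative


@dataclasses.dataclass
class GaitConditionResults:
    """Fitted pipeline: estimates, held-out metrics, and explanation access."""

    model: GaitConditionModel
    split: classify.SplitResult
    selection: select.SelectionResult
    scaler: preprocess.ScalerParams
    normative: derive.NormativeReference
    bundle: ModelBundle
    metrics: dict[str, classify.MetricsReport]
    train_table: pd.DataFrame
    test_table: pd.DataFrame
    label_guard: GuardedLabels
    config_hash: str

    @property
    def selected_features(self) -> list[str]:
        return self.selection.final_subset

    @property
    def vote_weights(self) -> dict[str, float]:
        return {n: float(w) for n, w in
                zip(classify.MODEL_NAMES, self.bundle.weights)}

    def macro_metrics(self) -> pd.DataFrame:
        """Four macro metrics per model (rows SVM/RF/LREGR/KNN/MV)."""
        return pd.DataFrame({name: rep.macro for name, rep in self.metrics.items()}).T

    def summary(self) -> str:
        """Text summary: configuration, selection, weights, held-out scores."""
        cfg = self.model.config
        lines = [
            "Gait condition classification results",
            "=" * 53,
            f"mode: {cfg.mode}    config hash: {self.config_hash}",
            f"subjects: {len(self.model.cohort)} "
            f"(train {len(self.split.train_ids)}, test {len(self.split.test_ids)}, "
            f"test ratio {self.split.ratio})",
            f"features: {len(self.selection.rfe_subset)} by RFE-CV, "
            f"{len(self.selection.importance_subset)} by forest importance, "
            f"{len(self.selected_features)} in the intersection",
            "vote weights: " + ", ".join(
                f"{n}={w:.3f}" for n, w in self.vote_weights.items()),
            "",
            "Held-out macro scores (one-vs-rest, unweighted average):",
            self.macro_metrics().round(3).to_string(),
        ]
        return "\n".join(lines)

    def metrics_json(self) -> str:
        """Deterministic JSON of per-class and macro metrics for all models."""
        payload = {
            "config_hash": self.config_hash,
            "mode": self.model.config.mode,
            "models": {
                name: {"macro": rep.macro, "per_class": rep.per_class,
                       "confusion": rep.confusion}
                for name, rep in self.metrics.items()},
            "selected_features": self.selected_features,
            "vote_weights": self.vote_weights,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def explain(self, conditions: Sequence[str] | None = None,
                models: tuple[str, ...] | None = None,
                n_samples: int | None = None) -> explain.RelevanceTable:
        """Per-condition top-feature relevance via the local surrogate.

        Subjects are drawn from the full cohort of each condition and
        explained for their true condition, in original feature units.
        """
        cfg = self.model.config
        conditions = list(conditions) if conditions is not None \
            else [c for c in PATHOLOGICAL_CONDITIONS
                  if c in set(self.model.cohort.labels())]
        full = pd.concat([self.train_table, self.test_table])
        original = preprocess.invert_scaler(full, self.scaler)
        return explain.explain_conditions(
            self.bundle, self.scaler,
            original.drop(columns="condition"), original["condition"],
            conditions=conditions, models=models,
            n_subjects=cfg.lime_subjects,
            n_samples=n_samples if n_samples is not None else cfg.lime_samples,
            seed=cfg.lime_seed, k=cfg.lime_top_k)

    def predict(self, X_scaled: pd.DataFrame, model: str = "MV") -> np.ndarray:
        return classify.predict_model(self.bundle, model, X_scaled)
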