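"""Perturbation-based local surrogate explanations (LIME family).

For one subject and one model, the explainer perturbs the feature vector by
resampling each feature from the quartile bins of a background (training)
table, weights every perturbed instance by an exponential proximity kernel
on the z-score-normalized distance to the explained instance, and fits a
weighted ridge surrogate to the model's predicted probability of the
target class. The surrogate's coefficients are the per-feature signed
weights; only their magnitudes are used for ranking.

Explanations are computed in the features' original units — the min-max
scaler is composed inside the prediction function — so a weight has units
of probability per original unit. Constant background features carry no
information to perturb and are excluded (weight 0, noted).

Per-condition relevance is aggregated as in the clinical workflow: sample
up to 20 subjects of each condition, rank features by mean absolute weight
across the sampled subjects per model, and report the top five together
with how many sampled subjects had the feature in their own top five.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .classify import MODEL_NAMES, ModelBundle, predict_soft_vote
from .features import describe_feature
from .preprocess import ScalerParams, apply_scaler


@dataclasses.dataclass
class Explanation:
    subject_id: str
    model: str
    target_class: str
    weights: dict[str, float]  # signed surrogate coefficients, original units
    n_samples: int
    seed: int
    excluded: list[str] = dataclasses.field(default_factory=list)

    def top_features(self, k: int = 5) -> list[str]:
        """The k features with largest |weight|; canonical-order tie-break."""
        order = {f: i for i, f in enumerate(self.weights)}
        return sorted(self.weights,
                      key=lambda f: (-abs(self.weights[f]), order[f]))[:k]


@dataclasses.dataclass
class QuartileSampler:
    """Per-feature quartile bins of the background, for perturbation draws."""

    edges: dict[str, np.ndarray]        # bin edges incl. background min/max
    frequencies: dict[str, np.ndarray]  # empirical bin frequencies
    scale: dict[str, float]             # background std (distance normalizer)
    constant: list[str]

    @classmethod
    def fit(cls, background: pd.DataFrame) -> "QuartileSampler":
        edges, freqs, scale, constant = {}, {}, {}, []
        for col in background.columns:
            x = background[col].to_numpy(dtype=float)
            qs = np.percentile(x, [0, 25, 50, 75, 100])
            e = np.unique(qs)
            if e.size < 2:
                constant.append(col)
                continue
            counts = np.histogram(x, bins=e)[0].astype(float)
            edges[col] = e
            freqs[col] = counts / counts.sum()
            scale[col] = float(x.std()) or 1.0
        return cls(edges=edges, frequencies=freqs, scale=scale, constant=constant)

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw n instances: per feature, pick a bin by its background
        frequency, then a uniform value within the bin."""
        cols = {}
        for col, e in self.edges.items():
            bins = rng.choice(e.size - 1, size=n, p=self.frequencies[col])
            u = rng.random(n)
            cols[col] = e[bins] + u * (e[bins + 1] - e[bins])
        return pd.DataFrame(cols)


def lime_explain_subject(bundle: ModelBundle, scaler: ScalerParams,
                         background: pd.DataFrame, x: pd.Series,
                         target_class: str, model: str = "MV",
                         n_samples: int = 5000, seed: int = 0,
                         kernel_width: float | None = None,
                         num_features: int | None = None) -> Explanation:
    """Explain one model's probability for *target_class* around *x*.

    *background* and *x* are in ORIGINAL units over the selected feature
    set; the scaler is composed inside the prediction function.
    Deterministic by *seed*.
    """
    feats = bundle.feature_names
    background = background[feats]
    sampler = QuartileSampler.fit(background)
    rng = np.random.default_rng(seed)

    perturbed = sampler.sample(n_samples, rng)
    for col in sampler.constant:  # constants held at the instance value
        perturbed[col] = float(x[col])
    perturbed = perturbed[feats]
    perturbed.iloc[0] = x[feats].astype(float)  # first row = the instance

    # proximity kernel on z-normalized distance
    active = [c for c in feats if c not in sampler.constant]
    sc = np.array([sampler.scale[c] for c in active])
    z = (perturbed[active].to_numpy() - x[active].to_numpy(dtype=float)) / sc
    dist = np.sqrt((z ** 2).sum(axis=1))
    width = kernel_width if kernel_width is not None else 0.75 * np.sqrt(len(active))
    kernel = np.exp(-(dist ** 2) / width ** 2)

    # model probability for the target class, scaler composed inside
    scaled = apply_scaler(perturbed, _subset_params(scaler, feats))
    ci = list(bundle.classes_).index(target_class)
    if model == "MV":
        proba = predict_soft_vote(bundle, scaled)[1][:, ci]
    else:
        proba = bundle.predict_proba(model, scaled)[:, ci]

    # Fit on the z-normalized design so the ridge penalty is unit-invariant;
    # dividing by the per-feature scale converts coefficients back to
    # probability-per-original-unit (exactly equivariant under rescaling).
    weights = _ridge_weights(z, proba, kernel) / sc
    if num_features is not None and num_features < len(active):
        rank = np.argsort(-np.abs(weights) * sc, kind="stable")[:num_features]
        sub = np.zeros_like(weights)
        sub[rank] = _ridge_weights(z[:, rank], proba, kernel) / sc[rank]
        weights = sub

    all_weights = {f: 0.0 for f in feats}
    all_weights.update({c: float(w) for c, w in zip(active, weights)})
    return Explanation(
        subject_id=str(x.name) if x.name is not None else "",
        model=model, target_class=target_class, weights=all_weights,
        n_samples=n_samples, seed=seed, excluded=list(sampler.constant))


def _ridge_weights(X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray,
                   alpha: float = 1.0) -> np.ndarray:
    ridge = Ridge(alpha=alpha)
    ridge.fit(X, y, sample_weight=sample_weight)
    return ridge.coef_


def _subset_params(scaler: ScalerParams, cols: list[str]) -> ScalerParams:
    return ScalerParams(min_=scaler.min_[cols], max_=scaler.max_[cols],
                        constant=scaler.constant[cols])


# ---------------------------------------------------------------------------
# aggregation

@dataclasses.dataclass
class RelevanceTable:
    """Per condition, per model: the top-k features by mean |weight|."""

    # condition -> model -> list of (feature, mean |weight|, top-5 count)
    entries: dict[str, dict[str, list[tuple[str, float, int]]]]
    k: int
    n_sampled: dict[str, int]


def aggregate_top_features(explanations: dict[str, dict[str, list[Explanation]]],
                           k: int = 5) -> RelevanceTable:
    """Aggregate per-subject explanations into a relevance table.

    *explanations* maps condition -> model -> one Explanation per sampled
    subject. Features are ranked by mean |weight| across subjects
    (canonical-order tie-break); the count is the number of sampled
    subjects whose individual top-k contains the feature.
    """
    entries: dict[str, dict[str, list[tuple[str, float, int]]]] = {}
    n_sampled: dict[str, int] = {}
    for condition, per_model in explanations.items():
        entries[condition] = {}
        for model, exps in per_model.items():
            n_sampled[condition] = len(exps)
            feats = list(exps[0].weights)
            order = {f: i for i, f in enumerate(feats)}
            mean_abs = {
                f: float(np.mean([abs(e.weights[f]) for e in exps])) for f in feats}
            top = sorted(feats, key=lambda f: (-mean_abs[f], order[f]))[:k]
            individual_tops = [set(e.top_features(k)) for e in exps]
            entries[condition][model] = [
                (f, mean_abs[f], sum(f in t for t in individual_tops)) for f in top]
    return RelevanceTable(entries=entries, k=k, n_sampled=n_sampled)


def sample_condition_subjects(labels: pd.Series, condition: str,
                              n_subjects: int = 20, seed: int = 0) -> list[str]:
    """Sample min(n, available) subject ids of one condition, w/o replacement."""
    ids = labels.index[labels == condition].tolist()
    rng = np.random.default_rng(seed)
    if len(ids) <= n_subjects:
        return ids
    return sorted(rng.choice(ids, size=n_subjects, replace=False).tolist())


def explain_conditions(bundle: ModelBundle, scaler: ScalerParams,
                       features_original: pd.DataFrame, labels: pd.Series,
                       conditions: list[str], models: tuple[str, ...] | None = None,
                       n_subjects: int = 20, n_samples: int = 5000,
                       seed: int = 0, k: int = 5) -> RelevanceTable:
    """Full aggregation loop over conditions, models and sampled subjects.

    The target class of every explanation is the subject's true condition;
    subjects are drawn from the full cohort of that condition.
    """
    models = models if models is not None else (*MODEL_NAMES, "MV")
    background = features_original[bundle.feature_names]
    explanations: dict[str, dict[str, list[Explanation]]] = {}
    for ci, condition in enumerate(conditions):
        ids = sample_condition_subjects(labels, condition, n_subjects,
                                        seed=seed + ci)
        explanations[condition] = {m: [] for m in models}
        for si, sid in enumerate(ids):
            x = background.loc[sid]
            for model in models:
                explanations[condition][model].append(lime_explain_subject(
                    bundle, scaler, background, x, target_class=condition,
                    model=model, n_samples=n_samples,
                    seed=seed + 1000 * ci + si))
    return aggregate_top_features(explanations, k=k)


# ---------------------------------------------------------------------------
# reporting

def relevance_report(table: RelevanceTable) -> dict:
    """JSON-ready report: per condition, the union of per-model top-k
    features with per-model counts (the "bar length" analog)."""
    report: dict = {"k": table.k, "conditions": {}}
    for condition, per_model in table.entries.items():
        union: dict[str, dict] = {}
        for model, rows in per_model.items():
            for feature, mean_w, count in rows:
                slot = union.setdefault(feature, {
                    "feature": feature,
                    "description": describe_feature(feature),
                    "counts": {}, "mean_abs_weight": {}})
                slot["counts"][model] = count
                slot["mean_abs_weight"][model] = mean_w
        report["conditions"][condition] = {
            "n_sampled": table.n_sampled.get(condition, 0),
            "features": sorted(union.values(),
                               key=lambda s: -sum(s["counts"].values())),
        }
    return report


def write_relevance_report(table: RelevanceTable, path: str | Path) -> None:
    """Write the JSON report plus a human-readable text table alongside."""
    report = relevance_report(table)
    path = Path(path)
    path.write_text(json.dumps(report, indent=2), encoding="utf-8")
    lines = []
    for condition, block in report["conditions"].items():
        lines.append(condition)
        lines.append("=" * len(condition))
        for slot in block["features"]:
            counts = ", ".join(f"{m}:{c}" for m, c in sorted(slot["counts"].items()))
            lines.append(f"  {slot['description']:<60s} [{counts}]")
        lines.append("")
    path.with_suffix(".txt").write_text("\n".join(lines), encoding="utf-8")
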