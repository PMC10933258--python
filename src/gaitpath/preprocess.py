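"""Median imputation of gait series and min-max feature scaling.

Missing grid values are filled with the median, at the same gait-cycle
index, of the other subjects — by default the subjects sharing the same
foot condition (class-conditional), falling back to the pooled median over
all training subjects when a (class, cell) has no observed value. Test
subjects, whose labels the pipeline must not read, are imputed with the
pooled medians. Imputation is fitted on training data and applied to
either partition; observed values are never altered.

Feature scaling is plain min-max to [0, 1], fitted on the training table
and applied unchanged to test data (values outside the training range are
not clipped). Constant training columns map to 0 and are flagged. A
natural-log transform (after shifting each column strictly positive) is
available but disabled by default: skewing brought no benefit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .angles import CANONICAL_ANGLES, SERIES_KINDS
from .io import GaitCohort


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# series-level median imputation

@dataclasses.dataclass
class ImputationModel:
    """Per-cell medians: class-conditional where observed, pooled always."""

    class_medians: dict[tuple[str, str, str], np.ndarray]  # (cond, angle, kind) -> 101
    pooled_medians: dict[tuple[str, str], np.ndarray]      # (angle, kind) -> 101


def fit_imputer(cohort: GaitCohort) -> ImputationModel:
    """Fit per-cell medians on a training cohort, ignoring missing cells."""
    if len(cohort) == 0:
        raise PreprocessError("cannot fit imputer on an empty cohort")
    class_medians: dict[tuple[str, str, str], np.ndarray] = {}
    pooled_medians: dict[tuple[str, str], np.ndarray] = {}
    conditions = sorted({s.condition for s in cohort.subjects})
    for angle in CANONICAL_ANGLES:
        for kind in SERIES_KINDS:
            stack = np.stack([
                s.angles[angle].mean_series if kind == "mean" else s.angles[angle].std_series
                for s in cohort.subjects])
            pooled = nanmedian_all_nan_ok(stack)
            if np.isnan(pooled).any():
                k_bad = int(np.flatnonzero(np.isnan(pooled))[0])
                raise PreprocessError(
                    f"cell never observed in training: {angle}/{kind} at k={k_bad}")
            pooled_medians[(angle, kind)] = pooled
            for cond in conditions:
                sub = np.stack([
                    s.angles[angle].mean_series if kind == "mean" else s.angles[angle].std_series
                    for s in cohort.subjects if s.condition == cond])
                with np.errstate(all="ignore"):
                    med = nanmedian_all_nan_ok(sub)
                # class cells with no observation fall back to pooled
                med = np.where(np.isnan(med), pooled, med)
                class_medians[(cond, angle, kind)] = med
    return ImputationModel(class_medians, pooled_medians)


def nanmedian_all_nan_ok(stack: np.ndarray) -> np.ndarray:
    """Columnwise nanmedian returning NaN (without warning) for empty columns."""
    out = np.full(stack.shape[1], np.nan)
    observed = ~np.isnan(stack)
    any_obs = observed.any(axis=0)
    if any_obs.any():
        out[any_obs] = np.nanmedian(stack[:, any_obs], axis=0)
    return out


def apply_imputer(cohort: GaitCohort, model: ImputationModel,
                  mode: str = "class_conditional") -> GaitCohort:
    """Fill every missing cell; returns a new cohort.

    ``class_conditional`` reads each subject's label (training data only);
    ``pooled`` ignores labels and is the default for test data.
    """
    if mode not in ("class_conditional", "pooled"):
        raise PreprocessError(f"unknown imputation mode {mode!r}")
    out = cohort.copy()
    for rec in out.subjects:
        if mode == "class_conditional" and not rec.condition:
            raise PreprocessError("class_conditional imputation requires labels")
        for angle in CANONICAL_ANGLES:
            series = rec.angles[angle]
            for kind, arr in (("mean", series.mean_series), ("std", series.std_series)):
                mask = np.isnan(arr)
                if not mask.any():
                    continue
                if mode == "class_conditional" and (rec.condition, angle, kind) in model.class_medians:
                    fill = model.class_medians[(rec.condition, angle, kind)]
                else:
                    fill = model.pooled_medians[(angle, kind)]
                arr[mask] = fill[mask]
    return out


# ---------------------------------------------------------------------------
# feature scaling

@dataclasses.dataclass
class ScalerParams:
    """Training-derived per-feature min/max for [0, 1] scaling."""

    min_: pd.Series
    max_: pd.Series
    constant: pd.Series  # bool per feature

    @property
    def columns(self) -> list[str]:
        return list(self.min_.index)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "condition"]


def fit_scaler(table: pd.DataFrame) -> ScalerParams:
    """Fit min-max parameters on a (training) feature table."""
    if len(table) == 0:
        raise PreprocessError("cannot fit scaler on an empty table")
    cols = _feature_columns(table)
    X = table[cols]
    mn, mx = X.min(axis=0), X.max(axis=0)
    return ScalerParams(min_=mn, max_=mx, constant=(mx - mn) == 0)


def _check_columns(table: pd.DataFrame, params: ScalerParams) -> list[str]:
    cols = _feature_columns(table)
    if set(cols) != set(params.columns):
        diff = set(cols) ^ set(params.columns)
        raise PreprocessError(f"scaler/table column mismatch: {sorted(diff)[:5]}")
    return cols


def apply_scaler(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Scale features to (x - min) / (max - min); constants map to 0.

    Values outside the training range are NOT clipped, so test data may
    fall outside [0, 1].
    """
    cols = _check_columns(table, params)
    out = table.copy()
    span = (params.max_ - params.min_).where(~params.constant, 1.0)
    out[cols] = (table[cols] - params.min_[cols]) / span[cols]
    out.loc[:, [c for c in cols if params.constant[c]]] = 0.0
    return out


def invert_scaler(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Undo :func:`apply_scaler`; identity on non-constant features."""
    cols = _check_columns(table, params)
    out = table.copy()
    span = (params.max_ - params.min_).where(~params.constant, 1.0)
    out[cols] = table[cols] * span[cols] + params.min_[cols]
    return out


def log_transform(table: pd.DataFrame, enabled: bool = False) -> pd.DataFrame:
    """Optional natural-log transform, per column, after a positive shift.

    Columns with min <= 0 are shifted by 1 - min so the transform is
    defined; monotone per column. Disabled by default.
    """
    if not enabled:
        return table
    out = table.copy()
    for col in _feature_columns(table):
        x = table[col].astype(float)
        mn = x.min()
        shift = 1.0 - mn if mn <= 0 else 0.0
        out[col] = np.log(x + shift)
    return out
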