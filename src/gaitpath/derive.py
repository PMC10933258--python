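"""Derived gait time series.

Two series are derived from each stride-averaged mean series ``U`` on the
101-point gait-cycle grid:

* the **first gradient** ``V[k] = (U[k+1] - U[k-1]) / 2`` — a discrete
  central difference capturing how the angle changes through the cycle.
  The endpoints k=0 and k=100 have no central difference, so ``V`` lives on
  k = 1..99 (length 99); no one-sided padding is invented.
* the **difference from normative** ``DN[k] = |U[k] - U_norm[k]|`` — the
  pointwise absolute deviation from a normative reference ``U_norm``
  computed per angle by averaging the mean series of all typically-developed
  ("Typical feet") subjects.

Both require fully observed series; impute missing values first.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .angles import CANONICAL_ANGLES, N_POINTS, TYPICAL
from .io import GaitCohort, SubjectRecord


class DerivationError(ValueError):
    pass


@dataclasses.dataclass
class NormativeReference:
    """Per-angle 101-point average over typical-feet subjects (U_norm)."""

    u_norm: dict[str, np.ndarray]

    def __post_init__(self):
        for angle, arr in self.u_norm.items():
            if arr.shape != (N_POINTS,) or not np.all(np.isfinite(arr)):
                raise DerivationError(f"normative series for {angle!r} invalid")


@dataclasses.dataclass
class DerivedSeriesSet:
    """All series of one subject for one angle, original and derived."""

    mean: np.ndarray            # U, k = 0..100
    std: np.ndarray             # k = 0..100
    first_gradient: np.ndarray  # V, k = 1..99 (length 99)
    diff_norm: np.ndarray       # DN, k = 0..100, >= 0


def compute_normative(cohort: GaitCohort) -> NormativeReference:
    """Average each angle's mean series over the typical-feet subjects."""
    typical = [s for s in cohort.subjects if s.condition == TYPICAL]
    if not typical:
        raise DerivationError("normative undefined: cohort has no 'Typical feet' subjects")
    u_norm: dict[str, np.ndarray] = {}
    for angle in CANONICAL_ANGLES:
        stack = np.stack([s.angles[angle].mean_series for s in typical])
        if np.isnan(stack).any():
            raise DerivationError("impute before derivation: missing values in typical-feet series")
        u_norm[angle] = stack.mean(axis=0)
    return NormativeReference(u_norm)


def first_gradient(series: np.ndarray) -> np.ndarray:
    """Central-difference derivative; input length 101, output length 99."""
    series = np.asarray(series, dtype=float)
    if series.shape != (N_POINTS,):
        raise DerivationError(f"series length {series.shape} != {N_POINTS}")
    if np.isnan(series).any():
        raise DerivationError("impute before derivation: series contains missing values")
    return 0.5 * (series[2:] - series[:-2])


def difference_from_normative(series: np.ndarray, u_norm: np.ndarray) -> np.ndarray:
    """Elementwise absolute deviation from the normative series."""
    series = np.asarray(series, dtype=float)
    u_norm = np.asarray(u_norm, dtype=float)
    if series.shape != u_norm.shape:
        raise DerivationError(f"length mismatch: {series.shape} vs {u_norm.shape}")
    if np.isnan(series).any() or np.isnan(u_norm).any():
        raise DerivationError("impute before derivation: missing values present")
    return np.abs(series - u_norm)


def derive_subject(record: SubjectRecord, normative: NormativeReference
                   ) -> dict[str, DerivedSeriesSet]:
    """Compute the full derived-series set for every angle of one subject."""
    out: dict[str, DerivedSeriesSet] = {}
    for angle in CANONICAL_ANGLES:
        s = record.angles[angle]
        out[angle] = DerivedSeriesSet(
            mean=s.mean_series,
            std=s.std_series,
            first_gradient=first_gradient(s.mean_series),
            diff_norm=difference_from_normative(s.mean_series, normative.u_norm[angle]),
        )
    return out
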