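"""Phase segmentation and the canonical scalar feature scheme.

The gait cycle is split at the foot-off instant (rounded half-up to the
nearest grid index r) into a stance window [0, r] and a swing window
[r, 100]; the boundary index belongs to both phases, so neither window can
be empty for any admissible foot-off.

Per functional angle, scalar features are computed from four series:

====================  =====================================================
series                statistics per phase
====================  =====================================================
mean                  max, timing of max, min, timing of min          (4)
std                   max, timing of max                              (2)
first gradient        max, timing of max, min, timing of min          (4)
diff. from normative  the four above + average over the phase         (5)
====================  =====================================================

15 features per phase, 30 over stance+swing, plus the range of motion of
the mean series over the whole cycle: 31 per angle, 372 over the 12 angles.
Two global features — the foot-off mean and its std — bring the total to
374. Timings are reported in % gait cycle (the grid index); ties go to the
earliest occurrence.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .angles import CANONICAL_ANGLES, N_POINTS, check_angle
from .derive import DerivedSeriesSet, NormativeReference, derive_subject
from .io import GaitCohort, SubjectRecord

SEP = "|"  # field separator inside canonical feature names

PHASES = ("stance", "swing")
#: statistic order inside each (series, phase) block
_BASIC_STATS = ("max", "timing_max", "min", "timing_min")

FOOT_OFF_MEAN = f"Foot_off{SEP}mean{SEP}full{SEP}value"
FOOT_OFF_STD = f"Foot_off{SEP}std{SEP}full{SEP}value"


@dataclasses.dataclass(frozen=True)
class PhaseWindows:
    """Inclusive index windows of the two gait phases."""

    r: int  # foot-off grid index

    @property
    def stance(self) -> tuple[int, int]:
        return (0, self.r)

    @property
    def swing(self) -> tuple[int, int]:
        return (self.r, N_POINTS - 1)

    def window(self, phase: str) -> tuple[int, int]:
        return self.stance if phase == "stance" else self.swing


def segment_phases(foot_off_mean: float) -> PhaseWindows:
    """Split the cycle at the foot-off instant (round-half-up)."""
    if not (0 < foot_off_mean < 100):
        raise ValueError(f"foot-off {foot_off_mean} outside (0, 100)")
    r = int(np.floor(foot_off_mean + 0.5))
    r = min(max(r, 1), 99)  # keep both windows non-degenerate on the grid
    return PhaseWindows(r=r)


def feature_name(angle: str, series: str, phase: str, statistic: str) -> str:
    """Canonical string encoding of a feature-name tuple (bijective)."""
    return SEP.join((angle, series, phase, statistic))


def parse_feature_name(name: str) -> tuple[str, str, str, str]:
    parts = name.split(SEP)
    if len(parts) != 4:
        raise ValueError(f"not a canonical feature name: {name!r}")
    return tuple(parts)  # type: ignore[return-value]


def enumerate_feature_names(angles: list[str] | tuple[str, ...] = CANONICAL_ANGLES
                            ) -> list[str]:
    """The canonical ordered feature enumeration: 31 per angle + 2 foot-off."""
    if not angles:
        raise ValueError("angle list is empty")
    names: list[str] = []
    for angle in angles:
        check_angle(angle)
        for series, stats in (
            ("mean", _BASIC_STATS),
            ("std", ("max", "timing_max")),
            ("first_gradient", _BASIC_STATS),
            ("diff_norm", _BASIC_STATS + ("avg_diff_norm",)),
        ):
            for phase in PHASES:
                for stat in stats:
                    names.append(feature_name(angle, series, phase, stat))
        names.append(feature_name(angle, "mean", "full", "range_of_motion"))
    names.append(FOOT_OFF_MEAN)
    names.append(FOOT_OFF_STD)
    return names


def describe_feature(name: str) -> str:
    """Human-readable prose for a canonical feature name."""
    angle, series, phase, stat = parse_feature_name(name)
    if angle == "Foot_off":
        return "Foot off (mean)" if series == "mean" else "Foot off (std)"
    series_prose = {
        "mean": "", "std": " |STD|",
        "first_gradient": " of First Gradient",
        "diff_norm": " of Difference from Normative",
    }[series]
    if stat == "range_of_motion":
        return f"Range of Motion of {angle}"
    stat_prose = {
        "max": "Max", "min": "Min",
        "timing_max": "Timing of Max", "timing_min": "Timing of Min",
        "avg_diff_norm": "Average",
    }[stat]
    return f"{stat_prose}{series_prose} of {angle} ({phase.capitalize()})"


def _window_stats(series: np.ndarray, lo: int, hi: int, k_offset: int = 0
                  ) -> dict[str, float]:
    """Extrema and their timings over the inclusive index window [lo, hi].

    *k_offset* maps array positions to gait-cycle indices (1 for the
    gradient series, which starts at k=1).
    """
    seg = series[lo:hi + 1]
    if seg.size == 0:
        raise ValueError("empty phase window")
    i_max = int(np.argmax(seg))   # first occurrence on ties
    i_min = int(np.argmin(seg))
    return {
        "max": float(seg[i_max]),
        "timing_max": float(lo + i_max + k_offset),
        "min": float(seg[i_min]),
        "timing_min": float(lo + i_min + k_offset),
    }


def extract_features(subject: SubjectRecord, derived: dict[str, DerivedSeriesSet],
                     windows: PhaseWindows) -> dict[str, float]:
    """Compute the full canonical feature vector for one subject."""
    values: dict[str, float] = {}
    for angle in CANONICAL_ANGLES:
        d = derived[angle]
        for series_name, arr, k0 in (
            ("mean", d.mean, 0),
            ("std", d.std, 0),
            ("first_gradient", d.first_gradient, 1),
            ("diff_norm", d.diff_norm, 0),
        ):
            if np.isnan(arr).any():
                raise ValueError(
                    f"impute before extraction: missing values in {angle}/{series_name}")
            for phase in PHASES:
                lo, hi = windows.window(phase)
                if k0 == 1:
                    # gradient defined on k=1..99: intersect, then shift to
                    # array positions
                    lo_g, hi_g = max(lo, 1), min(hi, 99)
                    stats = _window_stats(arr, lo_g - 1, hi_g - 1, k_offset=1)
                else:
                    stats = _window_stats(arr, lo, hi)
                keep = ("max", "timing_max") if series_name == "std" else _BASIC_STATS
                for stat in keep:
                    values[feature_name(angle, series_name, phase, stat)] = stats[stat]
                if series_name == "diff_norm":
                    values[feature_name(angle, "diff_norm", phase, "avg_diff_norm")] = \
                        float(np.mean(arr[lo:hi + 1]))
        rom = float(np.max(d.mean) - np.min(d.mean))
        values[feature_name(angle, "mean", "full", "range_of_motion")] = rom
    values[FOOT_OFF_MEAN] = float(subject.foot_off_mean)
    values[FOOT_OFF_STD] = float(subject.foot_off_std)
    return values


def extract_cohort_features(cohort: GaitCohort, normative: NormativeReference
                            ) -> pd.DataFrame:
    """Feature table: one row per subject, canonical columns + ``condition``."""
    columns = enumerate_feature_names()
    rows, index, labels = [], [], []
    for rec in cohort.subjects:
        try:
            derived = derive_subject(rec, normative)
            windows = segment_phases(rec.foot_off_mean)
            vec = extract_features(rec, derived, windows)
        except Exception as exc:
            raise type(exc)(f"subject {rec.subject_id!r}: {exc}") from exc
        rows.append([vec[c] for c in columns])
        index.append(rec.subject_id)
        labels.append(rec.condition)
    table = pd.DataFrame(rows, columns=columns,
                         index=pd.Index(index, name="subject_id"))
    table["condition"] = labels
    return table
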