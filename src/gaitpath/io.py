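"""Data model and file formats for gait cohorts and feature tables.

A cohort is a list of :class:`SubjectRecord`; each subject carries, per
functional angle, a stride-averaged *mean* series and a stride-variability
*std* series on the 101-point gait-cycle grid, plus the foot-off timing
(mean and std, in % cycle) and a condition label. Missing grid values are
represented as NaN in memory and as empty cells on disk.

Cohorts are stored as a single long-format CSV: one row per
``(subject, angle, kind, k)`` value plus a per-subject metadata section,
with ``#``-prefixed header/provenance lines and a trailing row-count
checksum comment so silently truncated files are rejected. Feature tables
are wide CSVs whose header is the canonical feature-name enumeration plus
``condition``.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .angles import (
    ALL_CONDITIONS,
    CANONICAL_ANGLES,
    N_POINTS,
    SERIES_KINDS,
)

_FLOAT_FMT = "%.6f"  # stored precision of all on-disk values


class ValidationError(ValueError):
    """A file or cohort violates the data contract."""


@dataclasses.dataclass
class AngleSeries:
    """Mean and std series (degrees) of one functional angle."""

    mean_series: np.ndarray  # length 101, NaN = missing
    std_series: np.ndarray   # length 101, >= 0 where present

    def __eq__(self, other) -> bool:  # NaN-aware equality
        if not isinstance(other, AngleSeries):
            return NotImplemented
        return _series_equal(self.mean_series, other.mean_series) and _series_equal(
            self.std_series, other.std_series
        )


@dataclasses.dataclass
class SubjectRecord:
    """One subject: 12 angle profiles, foot-off timing, condition label."""

    subject_id: str
    condition: str
    foot_off_mean: float  # % gait cycle, in (0, 100)
    foot_off_std: float
    angles: dict[str, AngleSeries]
    demographics: dict[str, float] | None = None  # age [yr], height [cm], weight [kg]

    def copy(self) -> "SubjectRecord":
        return SubjectRecord(
            subject_id=self.subject_id,
            condition=self.condition,
            foot_off_mean=self.foot_off_mean,
            foot_off_std=self.foot_off_std,
            angles={
                a: AngleSeries(s.mean_series.copy(), s.std_series.copy())
                for a, s in self.angles.items()
            },
            demographics=dict(self.demographics) if self.demographics else None,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SubjectRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.condition == other.condition
            and np.isclose(self.foot_off_mean, other.foot_off_mean)
            and np.isclose(self.foot_off_std, other.foot_off_std)
            and set(self.angles) == set(other.angles)
            and all(self.angles[a] == other.angles[a] for a in self.angles)
        )


@dataclasses.dataclass
class GaitCohort:
    """Ordered collection of subjects with provenance."""

    subjects: list[SubjectRecord]
    provenance: str = ""
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GaitCohort):
            return NotImplemented
        return len(self) == len(other) and all(
            a == b for a, b in zip(self.subjects, other.subjects)
        )

    def copy(self) -> "GaitCohort":
        return GaitCohort(
            [s.copy() for s in self.subjects], provenance=self.provenance, seed=self.seed
        )

    def labels(self) -> list[str]:
        return [s.condition for s in self.subjects]

    def subset(self, ids: Iterable[str]) -> "GaitCohort":
        wanted = set(ids)
        return GaitCohort(
            [s.copy() for s in self.subjects if s.subject_id in wanted],
            provenance=self.provenance,
            seed=self.seed,
        )


def _series_equal(a: np.ndarray, b: np.ndarray) -> bool:
    if a.shape != b.shape:
        return False
    both_nan = np.isnan(a) & np.isnan(b)
    close = np.isclose(a, b, atol=5e-7, equal_nan=True)
    return bool(np.all(close | both_nan))


# ---------------------------------------------------------------------------
# validation

def validate_cohort(cohort: GaitCohort) -> list[dict]:
    """Check every subject against the data contract.

    Returns a list of violations (empty iff valid); each violation is a dict
    with ``subject_id``, ``field`` and ``reason``. Violations are data, not
    exceptions, so callers can report them all at once.
    """
    violations: list[dict] = []

    def flag(sid: str, field: str, reason: str) -> None:
        violations.append({"subject_id": sid, "field": field, "reason": reason})

    seen: set[str] = set()
    for rec in cohort.subjects:
        if rec.subject_id in seen:
            flag(rec.subject_id, "subject_id", "duplicate subject id")
        seen.add(rec.subject_id)
        if rec.condition not in ALL_CONDITIONS:
            flag(rec.subject_id, "condition", f"unknown condition {rec.condition!r}")
        if not (0 < rec.foot_off_mean < 100):
            flag(rec.subject_id, "foot_off_mean", "foot-off out of range (0, 100)")
        missing = set(CANONICAL_ANGLES) - set(rec.angles)
        for angle in sorted(missing):
            flag(rec.subject_id, angle, "angle absent")
        extra = set(rec.angles) - set(CANONICAL_ANGLES)
        for angle in sorted(extra):
            flag(rec.subject_id, angle, "non-canonical angle name")
        for angle, series in rec.angles.items():
            for kind, arr in (("mean", series.mean_series), ("std", series.std_series)):
                if arr.shape != (N_POINTS,):
                    flag(rec.subject_id, f"{angle}/{kind}", f"series length {arr.shape} != {N_POINTS}")
                    continue
                finite = arr[~np.isnan(arr)]
                if np.any(~np.isfinite(finite)):
                    flag(rec.subject_id, f"{angle}/{kind}", "non-finite value")
                if kind == "std" and np.any(finite < 0):
                    flag(rec.subject_id, f"{angle}/{kind}", "negative std")
    return violations


def count_missing(cohort: GaitCohort) -> int:
    """Number of NaN grid cells across all mean/std series."""
    n = 0
    for rec in cohort.subjects:
        for series in rec.angles.values():
            n += int(np.isnan(series.mean_series).sum())
            n += int(np.isnan(series.std_series).sum())
    return n


# ---------------------------------------------------------------------------
# cohort CSV (long format)

_COHORT_COLUMNS = ["row_type", "subject_id", "field", "kind", "k", "value"]
_META_FIELDS = ("condition", "foot_off_mean", "foot_off_std", "age", "height", "weight")


def write_cohort(cohort: GaitCohort, path: str | Path) -> None:
    """Write a cohort as a long-format CSV with a row-count checksum footer."""
    rows: list[tuple] = []
    for rec in cohort.subjects:
        rows.append(("meta", rec.subject_id, "condition", "", "", rec.condition))
        rows.append(("meta", rec.subject_id, "foot_off_mean", "", "",
                     _FLOAT_FMT % rec.foot_off_mean))
        rows.append(("meta", rec.subject_id, "foot_off_std", "", "",
                     _FLOAT_FMT % rec.foot_off_std))
        for key, val in (rec.demographics or {}).items():
            rows.append(("meta", rec.subject_id, key, "", "", _FLOAT_FMT % val))
        for angle in CANONICAL_ANGLES:
            series = rec.angles[angle]
            for kind, arr in (("mean", series.mean_series), ("std", series.std_series)):
                for k in range(N_POINTS):
                    v = arr[k]
                    rows.append(("series", rec.subject_id, angle, kind, k,
                                 "" if np.isnan(v) else _FLOAT_FMT % v))
    buf = _stdio.StringIO()
    buf.write("# gaitpath cohort v1\n")
    if cohort.provenance:
        buf.write(f"# provenance: {cohort.provenance}\n")
    if cohort.seed is not None:
        buf.write(f"# seed: {cohort.seed}\n")
    buf.write(",".join(_COHORT_COLUMNS) + "\n")
    for row in rows:
        buf.write(",".join(_csv_cell(c) for c in row) + "\n")
    buf.write(f"# rows: {len(rows)}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _csv_cell(value) -> str:
    s = str(value)
    if "," in s or '"' in s:
        s = '"' + s.replace('"', '""') + '"'
    return s


def _read_checked_csv(path: str | Path) -> pd.DataFrame:
    """Read a ``#``-commented CSV, enforcing the trailing row-count checksum."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    footer = [ln for ln in lines if ln.startswith("# rows:")]
    if not footer:
        raise ValidationError(f"{path}: missing '# rows:' checksum footer (truncated file?)")
    declared = int(footer[-1].split(":", 1)[1])
    df = pd.read_csv(_stdio.StringIO(text), comment="#", keep_default_na=True,
                     na_values=[""])
    if len(df) != declared:
        raise ValidationError(
            f"{path}: row count {len(df)} != declared {declared} (truncated file?)")
    return df


def read_cohort(path: str | Path) -> GaitCohort:
    """Read a long-format cohort CSV; round-trips :func:`write_cohort` output."""
    df = _read_checked_csv(path)
    required = set(_COHORT_COLUMNS)
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}")

    meta = df[df["row_type"] == "meta"]
    series = df[df["row_type"] == "series"].copy()
    if len(series):
        series["k"] = series["k"].astype(int)
        bad_k = series[(series["k"] < 0) | (series["k"] > 100)]
        if len(bad_k):
            raise ValidationError(f"{path}: k outside 0..100 in rows {bad_k.index.tolist()[:5]}")
        bad_angle = series[~series["field"].isin(CANONICAL_ANGLES)]
        if len(bad_angle):
            names = sorted(bad_angle["field"].unique())
            raise ValidationError(f"{path}: non-canonical angle name(s) {names}")
        dup = series.duplicated(subset=["subject_id", "field", "kind", "k"])
        if dup.any():
            raise ValidationError(
                f"{path}: duplicate (subject, angle, kind, k) rows {series.index[dup].tolist()[:5]}")

    subjects: list[SubjectRecord] = []
    provenance, seed = _read_provenance(path)
    for sid in meta["subject_id"].drop_duplicates():
        m = meta[meta["subject_id"] == sid].set_index("field")["value"]
        demo = {k: float(m[k]) for k in ("age", "height", "weight") if k in m.index}
        angles: dict[str, AngleSeries] = {}
        sub = series[series["subject_id"] == sid]
        for angle in sorted(sub["field"].unique()):
            arrs = {}
            for kind in SERIES_KINDS:
                block = sub[(sub["field"] == angle) & (sub["kind"] == kind)]
                arr = np.full(N_POINTS, np.nan)
                vals = pd.to_numeric(block["value"], errors="coerce")
                arr[block["k"].to_numpy()] = vals.to_numpy()
                arrs[kind] = arr
            angles[angle] = AngleSeries(arrs["mean"], arrs["std"])
        missing_angles = set(CANONICAL_ANGLES) - set(angles)
        if missing_angles:
            raise ValidationError(
                f"{path}: subject {sid!r} missing angle(s) {sorted(missing_angles)}")
        subjects.append(SubjectRecord(
            subject_id=str(sid),
            condition=str(m["condition"]),
            foot_off_mean=float(m["foot_off_mean"]),
            foot_off_std=float(m["foot_off_std"]),
            angles=angles,
            demographics=demo or None,
        ))
    return GaitCohort(subjects, provenance=provenance, seed=seed)


def _read_provenance(path: str | Path) -> tuple[str, int | None]:
    provenance, seed = "", None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("# provenance:"):
            provenance = line.split(":", 1)[1].strip()
        elif line.startswith("# seed:"):
            seed = int(line.split(":", 1)[1])
        elif not line.startswith("#"):
            break
    return provenance, seed


# ---------------------------------------------------------------------------
# feature table CSV (wide format)

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (index = subject_id, columns = features + condition)."""
    buf = _stdio.StringIO()
    buf.write("# gaitpath feature table v1\n")
    table.to_csv(buf, index=True, index_label="subject_id", float_format=_FLOAT_FMT)
    buf.write(f"# rows: {len(table)}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_feature_table(path: str | Path, expected_columns: list[str] | None = None
                       ) -> pd.DataFrame:
    """Read a wide feature-table CSV.

    If *expected_columns* is given (the canonical enumeration plus
    ``condition``), the header must match it exactly; the error names the
    first mismatching column.
    """
    df = _read_checked_csv(path)
    if "subject_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'subject_id' column")
    df = df.set_index("subject_id")
    if expected_columns is not None:
        got = list(df.columns)
        if got != list(expected_columns):
            for i, exp in enumerate(expected_columns):
                if i >= len(got) or got[i] != exp:
                    found = got[i] if i < len(got) else "<absent>"
                    raise ValidationError(
                        f"{path}: header mismatch at column {i}: "
                        f"expected {exp!r}, found {found!r}")
            raise ValidationError(f"{path}: {len(got) - len(expected_columns)} extra column(s)")
    return df
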