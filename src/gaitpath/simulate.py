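"""Seed-reproducible synthetic gait cohorts.

The real retrospective cohort behind this pipeline is not publicly
deposited, so this module generates cohorts with the same structure:
seven condition groups with the reference subject counts (248 patients in
six pathological classes plus 100 typically-developed controls), twelve
functional angles with stride-averaged mean and stride-variability std
series on the 101-point gait-cycle grid, a foot-off near 60 % of the
cycle, demographics carried as metadata, and optional injected
missingness.

Every angle has a fixed smooth 3-harmonic base waveform (offset plus two
sinusoids with angle-specific amplitudes and phases); subjects add Gaussian
offset jitter, ±10 % amplitude jitter and ±2 %-cycle phase jitter. Each
pathological condition perturbs specific angles on top of the shared base —
an offset, an amplitude scaling toward/away from the cycle mean, a timing
shift, or std-envelope inflation — so that the planted (angle, series)
signal is recoverable downstream. Magnitudes are calibrated for signal
recoverability, not biofidelity.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .angles import (
    ALL_CONDITIONS,
    CANONICAL_ANGLES,
    DEFAULT_CLASS_COUNTS,
    DEMOGRAPHICS,
)
from .io import AngleSeries, GaitCohort, SubjectRecord


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class CohortConfig:
    """Conditions of a synthetic cohort draw."""

    class_counts: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_points: int = 101
    foot_off_mean_pct: float = 60.0   # % gait cycle
    foot_off_sd_pct: float = 2.0
    noise_sd_deg: float = 1.5         # per-subject offset jitter
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigurationError("class counts must be >= 0")
        unknown = set(self.class_counts) - set(ALL_CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown condition label(s) in class_counts: {sorted(unknown)}")
        if self.n_points < 3:
            raise ConfigurationError("n_points must be >= 3")
        if not (0 < self.foot_off_mean_pct < 100):
            raise ConfigurationError("foot_off_mean_pct must lie in (0, 100)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")


@dataclasses.dataclass(frozen=True)
class Effect:
    """One planted perturbation of an (angle, series) pair."""

    angle: str
    series: str      # "mean" | "std"
    phase: str       # "stance" | "swing" | "full"
    kind: str        # "offset" | "amplitude-scale" | "timing-shift"
    magnitude: float  # degrees (offset), factor (scale), % cycle (shift)

    def __post_init__(self):
        if self.angle not in CANONICAL_ANGLES:
            raise ConfigurationError(f"unknown angle {self.angle!r}")
        if self.series not in ("mean", "std"):
            raise ConfigurationError(f"bad series kind {self.series!r}")
        if self.phase not in ("stance", "swing", "full"):
            raise ConfigurationError(f"bad phase {self.phase!r}")
        if self.kind not in ("offset", "amplitude-scale", "timing-shift"):
            raise ConfigurationError(f"bad effect kind {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise ConfigurationError("effect magnitude must be finite")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """All planted effects of one condition."""

    condition: str
    effects: tuple[Effect, ...]


def condition_effect_registry() -> dict[str, EffectSpec]:
    """Default planted effects, one EffectSpec per pathological condition.

    The choices follow the clinical picture of each condition — a collapsed
    vs. exaggerated medial arch for planovalgus/cavovarus, an inward-turned
    forefoot for clubfoot, restricted hallux and ankle motion for hallux
    rigidus and for osteoarthritis with partial ankle replacement, and a
    hindfoot offset with inflated stride variability after a consolidated
    calcaneal fracture. Magnitudes are generator calibration, chosen for
    recoverability.
    """
    specs = {
        "Planovalgus": (
            Effect("Medial arch angle", "mean", "full", "offset", -8.0),),
        "Cavovarus": (
            Effect("Medial arch angle", "mean", "full", "offset", +8.0),),
        "Clubfoot": (
            Effect("Forefoot/ankle abduction", "mean", "full", "offset", -10.0),
            Effect("Forefoot/ankle supination", "mean", "full", "offset", +8.0)),
        "Hallux rigidus": (
            Effect("Hallux flexion", "mean", "full", "amplitude-scale", 0.45),
            Effect("Tibiotalar flexion", "mean", "full", "amplitude-scale", 0.70)),
        "Consolidated calcaneal fracture": (
            Effect("Subtalar inversion", "mean", "full", "offset", +6.0),
            Effect("Subtalar inversion", "std", "full", "amplitude-scale", 2.5)),
        "Tibiotalar osteoarthritis + partial ankle replacement": (
            Effect("Tibiotalar flexion", "mean", "full", "amplitude-scale", 0.55),
            Effect("Medial arch angle", "mean", "full", "offset", +4.0)),
    }
    return {cond: EffectSpec(cond, effects) for cond, effects in specs.items()}


# Fixed 3-harmonic base templates per angle: (offset deg, amp1, phase1,
# amp2, phase2). Smooth, periodic, angle-specific; package constants.
_BASE_TEMPLATES: dict[str, tuple[float, float, float, float, float]] = {
    "Tibiotalar flexion":        (5.0, 12.0, 0.3, 5.0, 1.1),
    "Medial arch inclination":   (20.0, 6.0, 1.0, 2.5, 0.2),
    "Medial arch angle":         (130.0, 8.0, 2.1, 3.0, 0.7),
    "Lateral arch angle":        (150.0, 5.0, 0.8, 2.0, 1.9),
    "Subtalar inversion":        (2.0, 7.0, 1.5, 3.0, 2.6),
    "Forefoot/ankle supination": (8.0, 6.0, 2.8, 2.0, 0.9),
    "Forefoot/midfoot supination": (4.0, 4.0, 0.5, 1.5, 1.7),
    "Forefoot/hindfoot abduction": (-3.0, 5.0, 1.2, 2.0, 0.4),
    "Forefoot/ankle abduction":  (-6.0, 7.0, 2.3, 2.5, 1.3),
    "Inter MT I-V angle":        (25.0, 4.0, 0.1, 1.5, 2.2),
    "Hallux adduction":          (10.0, 5.0, 1.8, 2.0, 3.0),
    "Hallux flexion":            (15.0, 14.0, 2.6, 6.0, 1.6),
}


def base_waveform(angle: str, n_points: int = 101) -> np.ndarray:
    """Shared smooth template for one angle (degrees vs. fraction of cycle)."""
    c0, a1, p1, a2, p2 = _BASE_TEMPLATES[angle]
    t = np.linspace(0.0, 1.0, n_points)
    return c0 + a1 * np.sin(2 * np.pi * t + p1) + a2 * np.sin(4 * np.pi * t + p2)


def _apply_phase_slice(n_points: int, phase: str, foot_off: float) -> slice:
    r = int(np.floor(foot_off + 0.5))
    r = min(max(r, 1), n_points - 2)
    if phase == "stance":
        return slice(0, r + 1)
    if phase == "swing":
        return slice(r, n_points)
    return slice(0, n_points)


def _apply_effect(series: np.ndarray, effect: Effect, foot_off: float) -> np.ndarray:
    out = series.copy()
    n = out.size
    win = _apply_phase_slice(n, effect.phase, foot_off)
    if effect.kind == "offset":
        out[win] = out[win] + effect.magnitude
    elif effect.kind == "amplitude-scale":
        seg = out[win]
        center = seg.mean()
        out[win] = center + effect.magnitude * (seg - center)
    else:  # timing-shift: circular shift by magnitude % of cycle
        shift = int(round(effect.magnitude / 100.0 * (n - 1)))
        out = np.roll(out, shift)
    return out


#: Per-(subject, effect) severity range: disease expression varies across
#: patients, from barely expressed to pronounced. Offsets and timing shifts
#: scale linearly with severity; amplitude-scale factors are exponentiated
#: (severity 0 would leave the waveform untouched).
SEVERITY_RANGE = (0.15, 1.85)


def _draw_subject(rng: np.random.Generator, config: CohortConfig, condition: str,
                  sid: str, effects: tuple[Effect, ...]) -> SubjectRecord:
    expressed = []
    for eff in effects:
        s = rng.uniform(*SEVERITY_RANGE)
        mag = eff.magnitude ** s if eff.kind == "amplitude-scale" else eff.magnitude * s
        expressed.append(Effect(eff.angle, eff.series, eff.phase, eff.kind, mag))
    effects = tuple(expressed)
    n = config.n_points
    t = np.linspace(0.0, 1.0, n)
    foot_off = float(np.clip(
        rng.normal(config.foot_off_mean_pct, config.foot_off_sd_pct), 1.0, 99.0))
    foot_off_std = float(abs(rng.normal(1.5, 0.5)))
    angles: dict[str, AngleSeries] = {}
    for angle in CANONICAL_ANGLES:
        c0, a1, p1, a2, p2 = _BASE_TEMPLATES[angle]
        offset_jit = rng.normal(0.0, config.noise_sd_deg)
        amp_jit = rng.uniform(0.9, 1.1)
        phase_jit = 2 * np.pi * rng.uniform(-0.02, 0.02)
        mean = (c0 + offset_jit
                + amp_jit * a1 * np.sin(2 * np.pi * t + p1 + phase_jit)
                + amp_jit * a2 * np.sin(4 * np.pi * t + p2 + phase_jit))
        std = np.abs(rng.normal(1.5, 0.5, size=n))
        for eff in effects:
            if eff.angle != angle:
                continue
            if eff.series == "mean":
                mean = _apply_effect(mean, eff, foot_off)
            else:
                std = np.abs(_apply_effect(std, eff, foot_off))
        angles[angle] = AngleSeries(mean_series=mean, std_series=std)
    demo_spec = DEMOGRAPHICS[condition]
    demographics = {
        key: float(max(rng.normal(mu, sd), 1.0))
        for key, (mu, sd) in demo_spec.items()
    }
    return SubjectRecord(
        subject_id=sid, condition=condition,
        foot_off_mean=foot_off, foot_off_std=foot_off_std,
        angles=angles, demographics=demographics,
    )


def generate_cohort(config: CohortConfig | None = None,
                    registry: dict[str, EffectSpec] | None = None) -> GaitCohort:
    """Draw a full cohort; identical (config, seed) gives identical output.

    Missingness is NOT injected here; call :func:`inject_missingness`
    explicitly (or rely on ``config.missing_rate`` via
    :func:`generate_default_cohort`).
    """
    config = config or CohortConfig()
    registry = condition_effect_registry() if registry is None else registry
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    idx = 0
    for condition in ALL_CONDITIONS:       # fixed order => determinism
        count = config.class_counts.get(condition, 0)
        spec = registry.get(condition)
        effects = spec.effects if spec is not None else ()
        for _ in range(count):
            idx += 1
            subjects.append(_draw_subject(
                rng, config, condition, f"subj-{idx:04d}", tuple(effects)))
    return GaitCohort(subjects,
                      provenance=f"synthetic cohort (seed={config.seed})",
                      seed=config.seed)


def inject_missingness(cohort: GaitCohort, rate: float, seed: int) -> GaitCohort:
    """Replace ~rate of all grid cells with NaN, uniformly at random.

    Labels, foot-off values and demographics are untouched; reproducible by
    *seed*; the input cohort is not modified.
    """
    if not (0 <= rate < 1):
        raise ConfigurationError("missing rate must lie in [0, 1)")
    out = cohort.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for rec in out.subjects:
        for angle in CANONICAL_ANGLES:
            series = rec.angles[angle]
            for arr in (series.mean_series, series.std_series):
                mask = rng.random(arr.size) < rate
                arr[mask] = np.nan
    return out


def generate_default_cohort(seed: int = 0, missing: bool = True) -> GaitCohort:
    """Default study-structure cohort; optional default 2 % missingness."""
    config = CohortConfig(seed=seed)
    cohort = generate_cohort(config)
    if missing and config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, seed=config.seed + 1)
    return cohort
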