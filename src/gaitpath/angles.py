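"""Canonical vocabulary for the gait data model.

The Heidelberg Foot Measurement Method (HFMM) describes foot kinematics with
twelve functional angles; every module in this package resolves angle names
through this single list. Cohorts carry one label per subject drawn from six
foot conditions plus a typically-developed control group.
"""

from __future__ import annotations

#: The 12 HFMM functional angles, in canonical order.
CANONICAL_ANGLES: tuple[str, ...] = (
    "Tibiotalar flexion",
    "Medial arch inclination",
    "Medial arch angle",
    "Lateral arch angle",
    "Subtalar inversion",
    "Forefoot/ankle supination",
    "Forefoot/midfoot supination",
    "Forefoot/hindfoot abduction",
    "Forefoot/ankle abduction",
    "Inter MT I-V angle",
    "Hallux adduction",
    "Hallux flexion",
)

#: Label of the typically-developed control group.
TYPICAL = "Typical feet"

#: The six pathological foot conditions, in canonical order.
PATHOLOGICAL_CONDITIONS: tuple[str, ...] = (
    "Tibiotalar osteoarthritis + partial ankle replacement",
    "Planovalgus",
    "Consolidated calcaneal fracture",
    "Hallux rigidus",
    "Clubfoot",
    "Cavovarus",
)

#: All condition labels, controls last.
ALL_CONDITIONS: tuple[str, ...] = PATHOLOGICAL_CONDITIONS + (TYPICAL,)

#: Subject count per condition in the reference cohort structure.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "Tibiotalar osteoarthritis + partial ankle replacement": 58,
    "Planovalgus": 64,
    "Consolidated calcaneal fracture": 20,
    "Hallux rigidus": 40,
    "Clubfoot": 41,
    "Cavovarus": 25,
    TYPICAL: 100,
}

#: Demographic (mean, sd) per condition: age [yr], height [cm], weight [kg].
#: Carried as subject metadata only; never used as classifier input.
DEMOGRAPHICS: dict[str, dict[str, tuple[float, float]]] = {
    "Tibiotalar osteoarthritis + partial ankle replacement": {
        "age": (57.9, 11.7), "height": (170.5, 8.6), "weight": (82.6, 17.7)},
    "Planovalgus": {
        "age": (31.3, 15.6), "height": (171.9, 12.4), "weight": (71.7, 20.1)},
    "Consolidated calcaneal fracture": {
        "age": (52.5, 10.4), "height": (178.0, 8.2), "weight": (86.6, 11.7)},
    "Hallux rigidus": {
        "age": (58.6, 8.2), "height": (168.2, 9.6), "weight": (74.8, 13.3)},
    "Clubfoot": {
        "age": (11.8, 9.3), "height": (140.1, 28.2), "weight": (41.5, 21.8)},
    "Cavovarus": {
        "age": (19.5, 14.9), "height": (161.0, 18.9), "weight": (59.7, 23.1)},
    TYPICAL: {
        "age": (24.0, 15.2), "height": (159.8, 23.7), "weight": (55.6, 23.9)},
}

#: Number of samples per cycle-normalized series (0..100 % gait cycle).
N_POINTS = 101

#: Series kinds stored per angle.
SERIES_KINDS = ("mean", "std")


def check_angle(name: str) -> str:
    """Return *name* if canonical, else raise ``ValueError``."""
    if name not in CANONICAL_ANGLES:
        raise ValueError(f"unknown functional angle: {name!r}")
    return name


def check_condition(label: str) -> str:
    """Return *label* if it is a known condition, else raise ``ValueError``."""
    if label not in ALL_CONDITIONS:
        raise ValueError(f"unknown foot condition label: {label!r}")
    return label
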