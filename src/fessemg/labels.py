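"""Canonical label sets for lower-limb motions and muscle-fatigue states.

The recognition problem is a joint one: six lower-limb motions (three daily
activities plus three rehabilitation exercises performed under functional
electrical stimulation) and three Borg-RPE-derived fatigue bands. Fatigue
states other than ``no_fatigue`` only occur for the rehabilitation exercises.
"""

from __future__ import annotations

MOTIONS: tuple[str, ...] = (
    "sitting",
    "walking",
    "climbing_stairs",
    "ankle_dorsiflexion",
    "ankle_plantarflexion",
    "cycling",
)

DAILY_MOTIONS: tuple[str, ...] = ("sitting", "walking", "climbing_stairs")

REHAB_MOTIONS: tuple[str, ...] = (
    "ankle_dorsiflexion",
    "ankle_plantarflexion",
    "cycling",
)

#: Borg CR10 bands: 0-3 no fatigue, 4-6 medium, 7-10 extreme.
FATIGUE_LEVELS: tuple[str, ...] = ("no_fatigue", "medium", "extreme")

MOTION_INDEX = {name: i for i, name in enumerate(MOTIONS)}
FATIGUE_INDEX = {name: i for i, name in enumerate(FATIGUE_LEVELS)}


def validate_motion(label: str) -> str:
    if label not in MOTION_INDEX:
        raise ValueError(
            f"unknown motion label {label!r}; expected one of {MOTIONS}"
        )
    return label


def validate_fatigue(label: str) -> str:
    if label not in FATIGUE_INDEX:
        raise ValueError(
            f"unknown fatigue label {label!r}; expected one of {FATIGUE_LEVELS}"
        )
    return label
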