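"""Movement-task vocabulary shared across the pipeline.

The assessment battery consists of six upper-body tasks drawn from the motor
section of the MDS-UPDRS: four *kinetic* tasks that prompt ~10 repetitions of
a movement (finger tapping, open-close hand, hand flip, finger to nose) and
two *stationary* postures held for 10 s (both hands out, resting hands).
"""

from __future__ import annotations

# Task codes in battery order.
FT = "FT"  # Finger Tapping: tap index finger on thumb 10 times
OC = "OC"  # Open and Close Hand: open the hand 10 times
HF = "HF"  # Hand Flip: palm up/down alternately 10 times
HH = "HH"  # Both Hands Out: arms out, palms down, 10 s
FN = "FN"  # Finger to Nose: nose-to-screen pointing, 10 times
RH = "RH"  # Resting Hands: arms at rest, 10 s

TASK_ORDER: tuple[str, ...] = (FT, OC, HF, HH, FN, RH)
TASK_CODES: frozenset[str] = frozenset(TASK_ORDER)

KINETIC_TASKS: frozenset[str] = frozenset({FT, OC, HF, FN})
STATIONARY_TASKS: frozenset[str] = frozenset({HH, RH})

#: Stationary-posture hold duration in seconds.
STATIONARY_DURATION_S = 10.0

#: Default repetition count for kinetic tasks.
DEFAULT_REPETITIONS = 10

HANDS: tuple[str, str] = ("left", "right")

#: The 11 value channels of one sensor frame, in wire order.
CHANNELS: tuple[str, ...] = (
    "ax", "ay", "az",          # wrist accelerometer (g)
    "gx", "gy", "gz",          # wrist gyroscope (deg/s)
    "pitch", "roll",           # attitude, AHRS-computed on device (deg)
    "flex_index", "flex_thumb", "flex_middle",  # finger flexion (ADC volts)
)

#: Alias map canonicalizing flexion channel labels ("ring" is sometimes used
#: for the third sensor in deployment notes; the canonical label is middle).
FLEXION_ALIASES: dict[str, str] = {
    "flex0": "flex_index",
    "flex1": "flex_thumb",
    "flex2": "flex_middle",
    "index": "flex_index",
    "thumb": "flex_thumb",
    "middle": "flex_middle",
    "ring": "flex_middle",
}

#: Primary analysis channel per task, used for activity detection and
#: peak-valley analysis.  Flexion carries fine finger movement (FT, OC);
#: attitude carries gross arm movement (HF, FN) and posture (HH, RH).
PRIMARY_CHANNEL: dict[str, str] = {
    FT: "flex_index",
    OC: "flex_index",
    HF: "roll",
    FN: "pitch",
    HH: "pitch",
    RH: "pitch",
}

#: Channels feeding feature extraction per task.
FEATURE_CHANNELS: dict[str, tuple[str, ...]] = {
    FT: ("flex_index",),
    OC: ("flex_index", "flex_thumb", "flex_middle"),
    HF: ("pitch", "roll"),
    FN: ("pitch", "roll"),
    HH: ("pitch", "roll", "gyro_mag"),
    RH: ("pitch", "roll", "gyro_mag"),
}


def validate_task(task: str) -> str:
    if task not in TASK_CODES:
        raise ValueError(f"unknown task code {task!r}; expected one of {sorted(TASK_CODES)}")
    return task


def validate_hand(hand: str) -> str:
    if hand not in HANDS:
        raise ValueError(f"unknown hand {hand!r}; expected 'left' or 'right'")
    return hand


def is_kinetic(task: str) -> bool:
    return validate_task(task) in KINETIC_TASKS
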