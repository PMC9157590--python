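"""Closed-form phenotype scores.

Novel-object discrimination index, Y-maze spontaneous-alternation
percentage, CCK-8 cell survival rate from plate absorbances, and the
0–5 renal tubule-injury rubric.
"""

from __future__ import annotations

from typing import Sequence

__all__ = [
    "discrimination_index",
    "alternation_percent",
    "cell_survival_rate",
    "tubule_injury_score",
]

ARM_LABELS = {1, 2, 3}


def discrimination_index(new_time: float, old_time: float) -> float:
    """Novel-object discrimination index in [-1, 1].

    DI = (new - old) / (new + old), with times in seconds spent exploring
    the novel and familiar object. +1 means exclusive interest in the
    novel object, 0 no preference.
    """
    if new_time < 0 or old_time < 0:
        raise ValueError("exploration times must be >= 0")
    total = new_time + old_time
    if total == 0:
        raise ValueError("both exploration times are zero; DI undefined")
    return (new_time - old_time) / total


def alternation_percent(sequence: Sequence[int]) -> float:
    """Y-maze spontaneous alternation percentage.

    An alternation is a window of three *consecutive* arm entries visiting
    three distinct arms (e.g. 1,2,3 or 1,3,2); the maximum possible is the
    number of entries minus 2. Entries are taken as recorded — repeated
    entries into the same arm are not collapsed.
    """
    seq = list(sequence)
    if len(seq) < 3:
        raise ValueError(f"need at least 3 arm entries, got {len(seq)}")
    invalid = sorted({a for a in seq if a not in ARM_LABELS})
    if invalid:
        raise ValueError(f"invalid arm labels {invalid}; expected {sorted(ARM_LABELS)}")
    windows = len(seq) - 2
    alternations = sum(
        1 for i in range(windows) if len(set(seq[i : i + 3])) == 3
    )
    return 100.0 * alternations / windows


def cell_survival_rate(
    od_treatment: float, od_control: float, od_blank: float
) -> float:
    """CCK-8 cell survival rate (%) from 450 nm absorbances.

    survival = (OD_treatment - OD_blank) / (OD_control - OD_blank) x 100.
    """
    denom = od_control - od_blank
    if denom <= 0:
        raise ValueError(
            f"control absorbance ({od_control}) must exceed blank ({od_blank})"
        )
    return 100.0 * (od_treatment - od_blank) / denom


def tubule_injury_score(percent_damaged: float) -> int:
    """Renal tubule-injury score on the 0-5 rubric.

    0 = no damaged tubules; 1 = under 20% damaged; 2 = 20-40%; 3 = 40-60%;
    4 = 60-80%; 5 = 80% or more. Boundary percentages fall in the upper
    bin (lower-closed intervals), so exactly 20% scores 2 and exactly 80%
    scores 5.
    """
    if not 0 <= percent_damaged <= 100:
        raise ValueError(f"percent damaged must be in [0, 100], got {percent_damaged}")
    if percent_damaged == 0:
        return 0
    if percent_damaged < 20:
        return 1
    if percent_damaged < 40:
        return 2
    if percent_damaged < 60:
        return 3
    if percent_damaged < 80:
        return 4
    return 5
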