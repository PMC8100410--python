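"""Mini-Mental State Examination (MMSE) severity staging.

The MMSE is a 0-30 integer cognitive screen; lower scores mean worse
impairment.  Scores are binned into four ordinal severity classes:

    low      25-30   (little or no measurable impairment)
    mild     20-25
    moderate 10-20
    severe    0-10

The published bands share their boundary scores (25, 20, 10).  By
default each shared boundary is assigned to the *less* impaired class
(25 -> low, 20 -> mild, 10 -> moderate), matching common clinical usage;
the opposite convention is available via ``boundary="more_severe"``.
"""

from __future__ import annotations

from collections import Counter
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SeverityClass", "CLASS_NAMES", "mmse_band", "severity_from_mmse", "label_cohort"]


class SeverityClass(IntEnum):
    """Ordinal severity, least to most impaired."""

    LOW = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


CLASS_NAMES: tuple[str, str, str, str] = ("low", "mild", "moderate", "severe")

# inclusive integer score bands under each boundary convention
_BANDS = {
    "less_severe": {
        SeverityClass.LOW: (25, 30),
        SeverityClass.MILD: (20, 24),
        SeverityClass.MODERATE: (10, 19),
        SeverityClass.SEVERE: (0, 9),
    },
    "more_severe": {
        SeverityClass.LOW: (26, 30),
        SeverityClass.MILD: (21, 25),
        SeverityClass.MODERATE: (11, 20),
        SeverityClass.SEVERE: (0, 10),
    },
}


def mmse_band(cls: SeverityClass, boundary: str = "less_severe") -> tuple[int, int]:
    """Inclusive (lo, hi) integer MMSE range generating class ``cls``."""
    return _BANDS[boundary][SeverityClass(cls)]


def severity_from_mmse(score: int, boundary: str = "less_severe") -> SeverityClass:
    """Map one integer MMSE score in [0, 30] to its severity class."""
    if boundary not in _BANDS:
        raise ValueError(f"unknown boundary convention {boundary!r}")
    if isinstance(score, bool) or not isinstance(score, (int, float, np.integer, np.floating)):
        raise ValueError(f"MMSE score must be an integer, got {score!r}")
    if not float(score).is_integer():
        raise ValueError(f"MMSE score must be an integer, got {score!r}")
    score = int(score)
    if not 0 <= score <= 30:
        raise ValueError(f"MMSE score must lie in [0, 30], got {score}")
    for cls, (lo, hi) in _BANDS[boundary].items():
        if lo <= score <= hi:
            return cls
    raise AssertionError("unreachable: bands cover [0, 30]")


def label_cohort(scores: Iterable[int], boundary: str = "less_severe"
                 ) -> tuple[list[SeverityClass], dict[SeverityClass, int]]:
    """Elementwise severity labels plus a 4-way class count summary."""
    labels: list[SeverityClass] = []
    for idx, s in enumerate(scores):
        try:
            labels.append(severity_from_mmse(s, boundary))
        except ValueError as err:
            raise ValueError(f"invalid MMSE score at index {idx}: {err}") from err
    counts = Counter(labels)
    return labels, {cls: counts.get(cls, 0) for cls in SeverityClass}
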