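"""Domain types shared across the package.

Glucose is carried in mmol/L throughout; the Clarke/Parkes grids convert
to mg/dL internally. Timestamps are naive local datetimes at minute
resolution (single-site wearable data; no timezone arithmetic).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

#: Physiologic sensor range in mmol/L; readings outside are rejected at I/O.
GLUCOSE_MIN = 1.0
GLUCOSE_MAX = 30.0

#: Maximum capillary-to-sensor pairing gap in minutes.
MAX_PAIR_GAP_MIN = 3.0


class ValidationError(ValueError):
    """Raised when input data violates a domain invariant."""


@dataclass(frozen=True)
class Participant:
    """Cohort member metadata.

    gold_score is the 7-point hypoglycemia-awareness scale (>=4 indicates
    impaired awareness); dafne_score is the 3-point symptomatic-threshold
    scale (2-3 indicate impaired awareness).
    """

    participant_id: str
    age: int
    sex: str  # "male" | "female"
    gold_score: int
    dafne_score: int
    treatment: str  # "MDI" | "pump"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 1 <= self.gold_score <= 7:
            raise ValidationError(f"gold_score must be in 1..7, got {self.gold_score}")
        if not 1 <= self.dafne_score <= 3:
            raise ValidationError(f"dafne_score must be in 1..3, got {self.dafne_score}")
        if self.treatment not in ("MDI", "pump"):
            raise ValidationError(f"treatment must be 'MDI' or 'pump', got {self.treatment!r}")


@dataclass
class CGMTrace:
    """One participant's sensor glucose series at nominal 15-min cadence.

    ``readings`` is a DataFrame with columns ``timestamp`` (datetime64) and
    ``glucose`` (mmol/L), sorted by timestamp with no duplicates. Gaps are
    allowed; downstream episode detection treats them as run breaks.
    """

    participant_id: str
    readings: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ts = self.readings["timestamp"]
        if ts.duplicated().any():
            dup = ts[ts.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate timestamp {dup} for participant {self.participant_id}"
            )
        if not ts.is_monotonic_increasing:
            self.readings = self.readings.sort_values("timestamp", ignore_index=True)

    def __len__(self) -> int:
        return len(self.readings)


@dataclass(frozen=True)
class SleepRecord:
    """Self-reported sleep quality for the night ending on ``date``.

    ``score`` is the 5-point Likert response to "How well did you sleep
    last night?" (1 = very poorly, 5 = very well), reported on the morning
    of ``date``.
    """

    participant_id: str
    date: dt.date
    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise ValidationError(f"sleep score must be in 1..5, got {self.score}")


@dataclass(frozen=True)
class PairedReading:
    """A capillary reference reading matched to a sensor reading.

    ``time_gap`` is the absolute pairing gap in minutes (<= 3 by
    construction).
    """

    capillary: float
    sensor: float
    time_gap: float

    def __post_init__(self) -> None:
        if self.capillary <= 0 or self.sensor <= 0:
            raise ValidationError("paired glucose values must be positive")
        if self.time_gap > MAX_PAIR_GAP_MIN + 1e-9:
            raise ValidationError(
                f"pair gap {self.time_gap:.2f} min exceeds {MAX_PAIR_GAP_MIN} min"
            )
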