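"""Per-night nocturnal hypoglycemia metrics.

The nocturnal window is the half-open interval [00:00, 06:00) local time:
24 sensor readings expected at 15-min cadence (00:00 through 05:45).
Hypoglycemia is strictly below threshold (3.9 and 3.0 mmol/L); a single
below-threshold reading represents the 15-min interval starting at its
timestamp, so a run of k consecutive readings is an episode of 15*k min.
A missing expected reading (gap > cadence) breaks a run — no interpolation
across gaps. Nights with fewer than 20 in-window readings fail QC.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from noctglu.datatypes import CGMTrace

#: Nocturnal window bounds (hours, half-open).
WINDOW_START_HOUR = 0
WINDOW_END_HOUR = 6
#: Nominal sensor cadence in minutes.
CADENCE_MIN = 15.0
#: Minimum in-window readings for a night to pass QC (24 expected).
QC_MIN_READINGS = 20
#: Hypoglycemia thresholds, mmol/L (strictly below).
THRESHOLD_L1 = 3.9
THRESHOLD_L2 = 3.0
#: Time-in-range bounds, mmol/L (inclusive on both ends).
TIR_LOW = 3.9
TIR_HIGH = 10.0
#: Duration-quartile bin edges in minutes: 0 / 1-45 / 46-90 / 91-150 / >150.
QUARTILE_EDGES_MIN = (45.0, 90.0, 150.0)


@dataclass
class NightRecord:
    """In-window readings for one participant-night, with QC status."""

    participant_id: str
    date: dt.date
    glucose: np.ndarray  # mmol/L, window order
    minutes: np.ndarray  # minutes since 00:00 of `date`
    n_readings: int
    qc_pass: bool

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        base = pd.Timestamp(self.date)
        return base + pd.to_timedelta(self.minutes, unit="m")


@dataclass(frozen=True)
class HypoEpisode:
    """A maximal run of consecutive below-threshold readings."""

    threshold: float
    start_minute: float  # minutes since 00:00 of the night date
    n_steps: int
    duration: float  # minutes, = 15 * n_steps
    nadir: float  # mmol/L


@dataclass
class NightMetrics:
    """All per-night derived quantities."""

    participant_id: str
    date: dt.date
    n_readings: int
    nh39_present: bool
    nh39_episodes: int
    nh39_duration: float  # min
    nh39_auc: float  # mmol/L.min
    nh30_present: bool
    nh30_episodes: int
    nh30_duration: float
    nh30_auc: float
    mean_glucose: float  # mmol/L
    cv: float  # %, 100*SD/mean (sample SD, n-1)
    tir: float  # % of readings in [3.9, 10.0]
    level_class: str  # none | level1_only | level2
    duration_quartile: str  # Q0 | QI | QII | QIII | QIV
    sleep_score: int | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _require_qc(night: NightRecord) -> None:
    if not night.qc_pass:
        raise ValueError(
            f"night {night.participant_id}/{night.date} failed QC "
            f"({night.n_readings} < {QC_MIN_READINGS} readings)"
        )


def extract_night(trace: CGMTrace, date: dt.date) -> NightRecord:
    """Slice the nocturnal window [00:00, 06:00) of ``date`` from a trace.

    A reading stamped exactly 06:00 is excluded (half-open window). Empty
    nights are returned with ``qc_pass=False``, never raised.
    """
    start = pd.Timestamp(date)
    end = start + pd.Timedelta(hours=WINDOW_END_HOUR)
    ts = trace.readings["timestamp"]
    mask = (ts >= start) & (ts < end)
    sub = trace.readings.loc[mask]
    minutes = (sub["timestamp"] - start).dt.total_seconds().to_numpy() / 60.0
    glucose = sub["glucose"].to_numpy(dtype=float)
    n = len(glucose)
    return NightRecord(
        participant_id=trace.participant_id,
        date=date,
        glucose=glucose,
        minutes=minutes,
        n_readings=n,
        qc_pass=n >= QC_MIN_READINGS,
    )


def episode_runs(
    glucose: np.ndarray,
    threshold: float,
    minutes: np.ndarray | None = None,
) -> list[tuple[int, int, float]]:
    """Maximal below-threshold runs on a raw glucose array.

    Returns (start_index, n_steps, nadir) triples. Adjacent readings
    continue a run only if separated by <= the nominal cadence; a larger
    gap (missing reading) breaks the run. With ``minutes=None`` the array
    is assumed gap-free at nominal cadence.
    """
    runs: list[tuple[int, int, float]] = []
    start = -1
    for i, g in enumerate(glucose):
        if g < threshold:
            if start < 0:
                start = i
            elif minutes is not None and minutes[i] - minutes[i - 1] > CADENCE_MIN + 1e-9:
                # gap breaks the run even though both sides are below threshold
                seg = glucose[start:i]
                runs.append((start, len(seg), float(seg.min())))
                start = i
        elif start >= 0:
            seg = glucose[start:i]
            runs.append((start, len(seg), float(seg.min())))
            start = -1
    if start >= 0:
        seg = glucose[start:]
        runs.append((start, len(seg), float(seg.min())))
    return runs


def detect_episodes(night: NightRecord, threshold: float) -> list[HypoEpisode]:
    """Hypoglycemia episodes for one QC-passing night at ``threshold``.

    Each maximal run of k consecutive (cadence-adjacent) readings strictly
    below threshold is one episode of duration 15*k minutes; a single
    below-threshold reading already constitutes the >=15-min minimum.
    """
    _require_qc(night)
    out = []
    for start, n_steps, nadir in episode_runs(night.glucose, threshold, night.minutes):
        out.append(
            HypoEpisode(
                threshold=threshold,
                start_minute=float(night.minutes[start]),
                n_steps=n_steps,
                duration=CADENCE_MIN * n_steps,
                nadir=nadir,
            )
        )
    return out


def auc_below(night: NightRecord, threshold: float) -> float:
    """Hypoglycemia AUC: sum over readings g < threshold of (threshold - g) * 15.

    Units mmol/L.min; 0.0 when no reading is below threshold. Incorporates
    both depth and duration of the excursion.
    """
    _require_qc(night)
    return _auc_below_array(night.glucose, threshold)


def _auc_below_array(glucose: np.ndarray, threshold: float) -> float:
    deficit = threshold - glucose
    return float(deficit[deficit > 0].sum() * CADENCE_MIN)


def duration_quartile_bin(nh39_duration_min: float) -> str:
    """Bin an NH<3.9 duration into the study's quartile labels.

    Q0 = no hypoglycemia (0 min); QI 1-45; QII 46-90; QIII 91-150;
    QIV > 150 min.
    """
    if nh39_duration_min <= 0:
        return "Q0"
    for label, edge in zip(("QI", "QII", "QIII"), QUARTILE_EDGES_MIN):
        if nh39_duration_min <= edge:
            return label
    return "QIV"


def night_summary(night: NightRecord, sleep_score: int | None = None) -> NightMetrics:
    """Compute all per-night metrics for a QC-passing night."""
    _require_qc(night)
    g = night.glucose
    n = night.n_readings

    runs39 = episode_runs(g, THRESHOLD_L1, night.minutes)
    runs30 = episode_runs(g, THRESHOLD_L2, night.minutes)
    dur39 = CADENCE_MIN * sum(r[1] for r in runs39)
    dur30 = CADENCE_MIN * sum(r[1] for r in runs30)

    mean = float(g.mean())
    sd = float(g.std(ddof=1)) if n > 1 else 0.0
    cv = 100.0 * sd / mean if mean > 0 else math.nan
    tir = 100.0 * float(((g >= TIR_LOW) & (g <= TIR_HIGH)).sum()) / n

    if dur30 > 0:
        level = "level2"
    elif dur39 > 0:
        level = "level1_only"
    else:
        level = "none"

    return NightMetrics(
        participant_id=night.participant_id,
        date=night.date,
        n_readings=n,
        nh39_present=dur39 > 0,
        nh39_episodes=len(runs39),
        nh39_duration=dur39,
        nh39_auc=_auc_below_array(g, THRESHOLD_L1),
        nh30_present=dur30 > 0,
        nh30_episodes=len(runs30),
        nh30_duration=dur30,
        nh30_auc=_auc_below_array(g, THRESHOLD_L2),
        mean_glucose=mean,
        cv=cv,
        tir=tir,
        level_class=level,
        duration_quartile=duration_quartile_bin(dur39),
        sleep_score=sleep_score,
    )


def nights_table(pairs: Iterable[tuple[NightRecord, int]]) -> pd.DataFrame:
    """Tidy per-night metrics table from (night, sleep_score) pairs.

    One row per QC-passing participant-night, columns exactly the
    NightMetrics fields.
    """
    rows = [night_summary(night, score).to_dict() for night, score in pairs]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["participant_id", "date"], ignore_index=True)
    return df
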