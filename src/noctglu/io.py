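"""CSV readers/writers and night-score pairing.

Canonical flat-CSV interchange formats (device-export dialects are out of
scope):

- CGM / capillary: ``participant_id,timestamp,glucose_mmol_l`` (ISO-8601
  timestamps, naive local time)
- sleep diary:     ``participant_id,date,score``
- participants:    ``participant_id,age,sex,gold_score,dafne_score,treatment``
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from noctglu.datatypes import (
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    CGMTrace,
    Participant,
    SleepRecord,
    ValidationError,
)
from noctglu import metrics

logger = logging.getLogger("noctglu")

CGM_COLUMNS = ["participant_id", "timestamp", "glucose_mmol_l"]
SLEEP_COLUMNS = ["participant_id", "date", "score"]
PARTICIPANT_COLUMNS = ["participant_id", "age", "sex", "gold_score", "dafne_score", "treatment"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_cgm_csv(path) -> list[CGMTrace]:
    """Load sensor glucose traces, one CGMTrace per participant.

    Rows may arrive unsorted; each trace is returned sorted by timestamp.
    Duplicate (participant, timestamp) rows, unparseable timestamps and
    out-of-range glucose raise ValidationError naming the offending row.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, CGM_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise ValidationError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[row]!r} at row {row + 2}"
        )
    glu = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = glu.isna() | (glu <= 0)
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(
            f"{path}: non-positive or non-numeric glucose "
            f"{df['glucose_mmol_l'].iloc[row]!r} at row {row + 2}"
        )
    out_of_range = (glu < GLUCOSE_MIN) | (glu > GLUCOSE_MAX)
    if out_of_range.any():
        row = int(out_of_range.idxmax())
        raise ValidationError(
            f"{path}: glucose {glu.iloc[row]} mmol/L outside physiologic range "
            f"[{GLUCOSE_MIN}, {GLUCOSE_MAX}] at row {row + 2}"
        )
    dup = df.assign(_ts=ts).duplicated(subset=["participant_id", "_ts"])
    if dup.any():
        row = int(dup.idxmax())
        raise ValidationError(
            f"{path}: duplicate reading for participant "
            f"{df['participant_id'].iloc[row]} at {ts.iloc[row]} (row {row + 2})"
        )
    traces = []
    clean = pd.DataFrame(
        {"participant_id": df["participant_id"], "timestamp": ts, "glucose": glu}
    )
    for pid, grp in clean.groupby("participant_id", sort=True):
        readings = (
            grp[["timestamp", "glucose"]].sort_values("timestamp").reset_index(drop=True)
        )
        traces.append(CGMTrace(participant_id=pid, readings=readings))
    return traces


#: Capillary meter downloads share the CGM flat-CSV layout.
read_capillary_csv = read_cgm_csv


def write_cgm_csv(traces: Iterable[CGMTrace], path) -> None:
    frames = [
        t.readings.assign(participant_id=t.participant_id)[
            ["participant_id", "timestamp", "glucose"]
        ]
        for t in traces
    ]
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"glucose": "glucose_mmol_l"})
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_sleep_csv(path) -> list[SleepRecord]:
    """Load the daily sleep diary; scores outside 1..5 are rejected."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, SLEEP_COLUMNS, path)
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        row = int(dates.isna().idxmax())
        raise ValidationError(
            f"{path}: unparseable date {df['date'].iloc[row]!r} at row {row + 2}"
        )
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(scores.isna().idxmax())
        raise ValidationError(f"{path}: non-numeric score at row {row + 2}")
    records = []
    for i, (pid, date, score) in enumerate(
        zip(df["participant_id"], dates, scores.astype(int))
    ):
        try:
            records.append(SleepRecord(pid, date.date(), int(score)))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_sleep_csv(records: Iterable[SleepRecord], path) -> None:
    df = pd.DataFrame(
        [{"participant_id": r.participant_id, "date": r.date.isoformat(), "score": r.score}
         for r in records]
    )
    df.to_csv(path, index=False)


def read_participants_csv(path) -> list[Participant]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, PARTICIPANT_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                Participant(
                    participant_id=row["participant_id"],
                    age=int(row["age"]),
                    sex=str(row["sex"]),
                    gold_score=int(row["gold_score"]),
                    dafne_score=int(row["dafne_score"]),
                    treatment=str(row["treatment"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {int(i) + 2}: {exc}") from exc
    return out


def participants_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "age": p.age,
                "sex": p.sex,
                "gold_score": p.gold_score,
                "dafne_score": p.dafne_score,
                "treatment": p.treatment,
            }
            for p in participants
        ]
    )


def write_participants_csv(participants: Iterable[Participant], path) -> None:
    participants_frame(participants).to_csv(path, index=False)


def pair_by_night(
    traces: Iterable[CGMTrace], sleep_records: Iterable[SleepRecord]
) -> list[tuple[metrics.NightRecord, int]]:
    """Join QC-passing nocturnal windows to next-morning sleep scores.

    The score reported on morning D is paired with the window
    [00:00, 06:00) of date D — "How well did you sleep last night?" refers
    to the night ending that morning. Nights without a matching score and
    scores without a QC-passing night are dropped and logged, never fatal.
    """
    scores: dict[tuple[str, dt.date], int] = {}
    for rec in sleep_records:
        scores[(rec.participant_id, rec.date)] = rec.score

    pairs: list[tuple[metrics.NightRecord, int]] = []
    matched = set()
    for trace in traces:
        ts = trace.readings["timestamp"]
        dates = sorted({t.date() for t in ts})
        for date in dates:
            night = metrics.extract_night(trace, date)
            if night.n_readings == 0:
                continue
            if not night.qc_pass:
                logger.info(
                    "dropping night %s/%s: QC fail (%d readings)",
                    trace.participant_id, date, night.n_readings,
                )
                continue
            key = (trace.participant_id, date)
            if key not in scores:
                logger.info("dropping night %s/%s: no sleep score", *key)
                continue
            matched.add(key)
            pairs.append((night, scores[key]))
    for key in scores.keys() - matched:
        logger.info("dropping sleep score %s/%s: no qualifying night", *key)
    return pairs
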