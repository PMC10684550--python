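"""Sensor-vs-capillary accuracy: pairing, MARD, Clarke and Parkes grids.

Glucose enters in mmol/L and is converted to mg/dL (x 18.016, the molar
mass of glucose) for the grids, whose published boundaries are defined in
mg/dL. Boundary ties are assigned to the more favorable (earlier-letter)
zone so assignment is deterministic.

The Clarke (1987) grid is rule-based; the Parkes consensus grid for type
1 diabetes is a point-in-polygon test against the published boundary
coordinates (the same vertex table encoded by the standard R/Python
error-grid implementations), with zones nested A within B within C
within D within E over the 0-550 mg/dL square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from noctglu.datatypes import CGMTrace, PairedReading

__all__ = [
    "MGDL_PER_MMOL",
    "ZoneSummary",
    "clarke_zone",
    "mard",
    "pair_readings",
    "parkes_zone",
    "zone_summary",
    "sensor_accuracy_report",
]

#: mmol/L -> mg/dL conversion (molar mass of glucose), fixed here so the
#: grids are bit-reproducible.
MGDL_PER_MMOL = 18.016

_GRID_MAX = 550.0

# Parkes type-1-diabetes boundary polylines (reference x, estimate y; mg/dL).
_B_UPPER = [(0, 50), (30, 50), (140, 170), (280, 380), (430, 550)]
_B_LOWER = [(50, 0), (50, 30), (170, 145), (385, 300), (550, 450)]
_C_UPPER = [(0, 60), (30, 60), (50, 80), (70, 110), (260, 550)]
_C_LOWER = [(120, 0), (120, 30), (260, 130), (550, 250)]
_D_UPPER = [(0, 100), (25, 100), (50, 125), (80, 215), (125, 550)]
_D_LOWER = [(250, 0), (250, 40), (550, 150)]
_E_UPPER = [(0, 150), (35, 155), (50, 550)]


def _band_polygon(upper, lower):
    """Polygon between an upper and a lower boundary polyline."""
    ring = [(0.0, 0.0)]
    ring += [(float(x), float(y)) for x, y in lower]
    ring.append((_GRID_MAX, _GRID_MAX))
    ring += [(float(x), float(y)) for x, y in reversed(upper)]
    return Polygon(ring)


def _upper_only_polygon(upper):
    """Polygon below an upper boundary polyline, down to the x axis."""
    ring = [(0.0, 0.0), (_GRID_MAX, 0.0), (_GRID_MAX, _GRID_MAX)]
    ring += [(float(x), float(y)) for x, y in reversed(upper)]
    return Polygon(ring)


_PARKES_T1 = [
    ("A", prep(_band_polygon(_B_UPPER, _B_LOWER))),
    ("B", prep(_band_polygon(_C_UPPER, _C_LOWER))),
    ("C", prep(_band_polygon(_D_UPPER, _D_LOWER))),
    ("D", prep(_upper_only_polygon(_E_UPPER))),
]


def pair_readings(
    capillary: CGMTrace | pd.DataFrame,
    sensor: CGMTrace | pd.DataFrame,
    max_gap_min: float = 3.0,
) -> list[PairedReading]:
    """Match each capillary reading to its nearest-in-time sensor reading.

    Pairs with gap > ``max_gap_min`` (default 3 min) are discarded. A
    sensor reading may serve multiple capillary readings; pairing is not
    one-to-one.
    """
    cap = capillary.readings if isinstance(capillary, CGMTrace) else capillary
    sen = sensor.readings if isinstance(sensor, CGMTrace) else sensor
    if len(sen) == 0 or len(cap) == 0:
        return []
    sen_t = sen["timestamp"].to_numpy(dtype="datetime64[s]").astype("int64")
    sen_g = sen["glucose"].to_numpy(dtype=float)
    order = np.argsort(sen_t, kind="stable")
    sen_t, sen_g = sen_t[order], sen_g[order]

    cap_t = cap["timestamp"].to_numpy(dtype="datetime64[s]").astype("int64")
    cap_g = cap["glucose"].to_numpy(dtype=float)

    pairs = []
    idx = np.searchsorted(sen_t, cap_t)
    for i, (t, g) in enumerate(zip(cap_t, cap_g)):
        candidates = []
        if idx[i] > 0:
            candidates.append(idx[i] - 1)
        if idx[i] < len(sen_t):
            candidates.append(idx[i])
        # exact ties broken toward the earlier sensor reading
        j = min(candidates, key=lambda c: abs(sen_t[c] - t))
        gap_min = abs(sen_t[j] - t) / 60.0
        if gap_min <= max_gap_min + 1e-9:
            pairs.append(PairedReading(capillary=g, sensor=sen_g[j], time_gap=gap_min))
    return pairs


def mard(pairs: Sequence[PairedReading]) -> float:
    """Mean absolute relative difference, %.

    mean over pairs of |capillary - sensor| / capillary x 100; the
    denominator is the capillary reference, so the measure is asymmetric.
    """
    if len(pairs) == 0:
        raise ValueError("MARD requires at least one pair")
    vals = [abs(p.capillary - p.sensor) / p.capillary for p in pairs]
    return 100.0 * float(np.mean(vals))


def clarke_zone(reference: float, estimate: float) -> str:
    """Clarke (1987) error-grid zone for one (reference, estimate) pair in mmol/L.

    Implements the canonical zone rules (A: within 20% or both < 70
    mg/dL; E: hypo reported during true hyperglycemia or vice versa; C:
    overcorrection zones; D: failure to detect). Zone A's boundaries are
    inclusive, so points on the 20% lines take the favorable zone; the
    remaining boundaries follow the canonical published inequality
    directions (rule order A, E, C, D, else B).
    """
    if reference <= 0 or estimate <= 0:
        raise ValueError("glucose values must be positive")
    r = reference * MGDL_PER_MMOL
    e = estimate * MGDL_PER_MMOL

    if (r <= 70 and e <= 70) or (0.8 * r <= e <= 1.2 * r):
        return "A"
    if (r >= 180 and e <= 70) or (r <= 70 and e >= 180):
        return "E"
    if (70 <= r <= 290 and e >= r + 110) or (130 <= r <= 180 and e <= (7.0 / 5.0) * r - 182):
        return "C"
    if (
        (r >= 240 and 70 <= e <= 180)
        or (r <= 175.0 / 3.0 and 70 <= e <= 180)
        or (175.0 / 3.0 <= r <= 70 and e >= (6.0 / 5.0) * r)
    ):
        return "D"
    return "B"


def parkes_zone(reference: float, estimate: float) -> str:
    """Parkes consensus grid zone (type 1 diabetes) for values in mmol/L.

    Values beyond the published 550 mg/dL domain are clamped onto its
    edge before the point-in-polygon test.
    """
    if reference <= 0 or estimate <= 0:
        raise ValueError("glucose values must be positive")
    x = min(reference * MGDL_PER_MMOL, _GRID_MAX)
    y = min(estimate * MGDL_PER_MMOL, _GRID_MAX)
    pt = Point(x, y)
    for zone, poly in _PARKES_T1:
        if poly.intersects(pt):  # prepared intersects includes the boundary
            return zone
    return "E"


@dataclass
class ZoneSummary:
    """Error-grid zone counts/percentages plus MARD for a set of pairs."""

    grid: str  # "clarke" | "parkes_t1"
    counts: dict[str, int]
    percentages: dict[str, float]
    n_pairs: int
    mard: float

    def to_dict(self) -> dict:
        return {
            "grid": self.grid,
            "counts": self.counts,
            "percentages": self.percentages,
            "n_pairs": self.n_pairs,
            "mard": self.mard,
        }


def zone_summary(pairs: Sequence[PairedReading], grid: str = "clarke") -> ZoneSummary:
    """Assign every pair to exactly one zone and summarize."""
    if grid == "clarke":
        assign = clarke_zone
    elif grid == "parkes_t1":
        assign = parkes_zone
    else:
        raise ValueError(f"unknown grid {grid!r}; use 'clarke' or 'parkes_t1'")
    counts = {z: 0 for z in "ABCDE"}
    for p in pairs:
        counts[assign(p.capillary, p.sensor)] += 1
    n = len(pairs)
    pct = {z: (100.0 * c / n if n else 0.0) for z, c in counts.items()}
    return ZoneSummary(
        grid=grid, counts=counts, percentages=pct, n_pairs=n,
        mard=mard(pairs) if n else float("nan"),
    )


def sensor_accuracy_report(
    capillary_traces: Iterable[CGMTrace],
    cgm_traces: Iterable[CGMTrace],
    max_gap_min: float = 3.0,
) -> dict:
    """Per-participant pairing, pooled MARD and both grid summaries."""
    sensors = {t.participant_id: t for t in cgm_traces}
    pairs: list[PairedReading] = []
    for cap in capillary_traces:
        sen = sensors.get(cap.participant_id)
        if sen is None:
            continue
        pairs.extend(pair_readings(cap, sen, max_gap_min=max_gap_min))
    report = {
        "n_pairs": len(pairs),
        "mard": mard(pairs) if pairs else float("nan"),
        "clarke": zone_summary(pairs, "clarke").to_dict(),
        "parkes_t1": zone_summary(pairs, "parkes_t1").to_dict(),
    }
    return report
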