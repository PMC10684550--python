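"""Synthetic cohorts with known ground truth.

The generator emulates the four study inputs — nocturnal CGM traces,
morning sleep diaries, participant metadata, capillary meter downloads —
so every downstream stage is testable without patient data.

Nocturnal glucose is a participant-level baseline plus AR(1) noise over
the 24-reading window (00:00-05:45 at 15-min cadence). A night selected
for hypoglycemia (probability ``hypo_night_prob``) receives a smooth
excursion: half-cosine entry/exit ramps around a plateau held near the
drawn nadir for the drawn number of 15-min steps. Sleep scores are drawn
from a random-intercept proportional-odds model whose covariates are
computed by :mod:`noctglu.metrics` on the generated night — the generator
never re-derives metric definitions, so simulation truth and analysis
share one set of definitions. Capillary readings are sensor values
perturbed by multiplicative error calibrated to a target MARD.

Determinism: one global integer seed; the four random streams
(participants, glucose, sleep, capillary) are independent named
substreams spawned from it, so e.g. redrawing sleep scores under a
different effect vector leaves the glucose stream bit-identical.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from noctglu.datatypes import CGMTrace, Participant, SleepRecord
from noctglu import metrics
from noctglu.metrics import NightMetrics, NightRecord

_STREAMS = ("participants", "glucose", "sleep", "capillary")

#: Sensor clip range, mmol/L (span of the device output).
CLIP_LOW = 1.1
CLIP_HIGH = 27.8

#: Half-cosine ramp weights on each side of the excursion plateau.
_RAMP_W = (0.25, 0.75)
#: Uniform jitter (mmol/L) added above the nadir within the plateau.
_PLATEAU_JITTER = 0.2


@dataclass
class SyntheticConfig:
    """All knobs of the generative model, with study-scale defaults.

    Default effect sizes (``sleep_betas``, log-odds) correspond to an
    adjusted OR of 0.49 for presence of nocturnal hypoglycemia <3.9
    mmol/L, with small age and sex effects; cutpoints put the mean
    no-hypoglycemia sleep score near 3.5 on the 1-5 scale.
    """

    n_participants: int = 27
    nights_per_participant: int = 28
    seed: int = 0

    # participant-level mean nocturnal glucose, mmol/L
    baseline_mean: float = 8.3
    baseline_sd: float = 1.0
    # AR(1) noise around the baseline
    ar_rho: float = 0.7
    ar_sigma: float = 0.55

    # nocturnal hypoglycemia injection
    hypo_night_prob: float = 0.24
    hypo_two_episode_prob: float = 0.08       # second, shorter excursion
    hypo_duration_median_steps: float = 6.5   # plateau length, 15-min steps
    hypo_duration_log_sd: float = 0.65
    hypo_duration_max_steps: int = 20
    hypo_nadir_mean: float = 3.2             # mmol/L
    hypo_nadir_sd: float = 0.45
    hypo_nadir_range: tuple[float, float] = (2.0, 3.8)

    # ordinal sleep model: P(Y<=k) = logistic(cutpoint_k - eta),
    # eta = sum(beta_j * x_j) + u_i, u_i ~ N(0, sigma_u^2)
    sleep_betas: dict[str, float] = field(
        default_factory=lambda: {
            "nh39_present": math.log(0.49),
            "age": -0.02,
            "sex_female": 0.2,
        }
    )
    sleep_cutpoints: tuple[float, ...] = (-3.7, -2.4, -0.7, 1.45)
    sigma_u: float = 0.8

    # capillary pairing
    n_capillary_pairs: int = 518
    mard_target: float = 13.6  # % relative error scale

    def __post_init__(self) -> None:
        cp = tuple(self.sleep_cutpoints)
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("sleep_cutpoints must be strictly increasing")
        if not 0.0 <= self.hypo_night_prob <= 1.0:
            raise ValueError("hypo_night_prob must be in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sleep_cutpoints" in raw:
            raw["sleep_cutpoints"] = tuple(raw["sleep_cutpoints"])
        if "hypo_nadir_range" in raw:
            raw["hypo_nadir_range"] = tuple(raw["hypo_nadir_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["sleep_cutpoints"] = list(self.sleep_cutpoints)
        raw["hypo_nadir_range"] = list(self.hypo_nadir_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class SyntheticCohort:
    """Generated study inputs plus the ground-truth night table."""

    config: SyntheticConfig
    participants: list[Participant]
    traces: list[CGMTrace] | None
    sleep_records: list[SleepRecord]
    capillary: pd.DataFrame | None  # participant_id, timestamp, glucose_mmol_l
    night_table: pd.DataFrame       # NightMetrics fields + age/sex_female + sleep_score
    random_intercepts: dict[str, float]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, root.spawn(len(_STREAMS)))}


def _draw_duration_steps(config: SyntheticConfig, rng: np.random.Generator) -> int:
    raw = rng.lognormal(mean=math.log(config.hypo_duration_median_steps),
                        sigma=config.hypo_duration_log_sd)
    return int(np.clip(round(raw), 1, config.hypo_duration_max_steps))


def _draw_nadir(config: SyntheticConfig, rng: np.random.Generator) -> float:
    lo, hi = config.hypo_nadir_range
    for _ in range(100):
        m = rng.normal(config.hypo_nadir_mean, config.hypo_nadir_sd)
        if lo <= m <= hi:
            return float(m)
    return float(np.clip(m, lo, hi))


def night_glucose(
    config: SyntheticConfig,
    baseline: float,
    rng: np.random.Generator,
    force_hypo: bool | None = None,
) -> np.ndarray:
    """One night's 24-reading glucose array (mmol/L, 00:00-05:45).

    ``force_hypo`` overrides the Bernoulli(hypo_night_prob) selection
    (used by tests; the nightly draw is still consumed so the stream
    stays aligned).
    """
    n = 24
    sd_stat = config.ar_sigma / math.sqrt(max(1.0 - config.ar_rho**2, 1e-12)) \
        if config.ar_sigma > 0 else 0.0
    noise = np.empty(n)
    innov = rng.normal(0.0, 1.0, size=n)
    noise[0] = innov[0] * sd_stat
    for t in range(1, n):
        noise[t] = config.ar_rho * noise[t - 1] + innov[t] * config.ar_sigma
    g = baseline + noise

    selected = rng.random() < config.hypo_night_prob
    if force_hypo is not None:
        selected = force_hypo
    if selected:
        d = min(_draw_duration_steps(config, rng), n)
        start = int(rng.integers(0, n - d + 1))
        _inject_excursion(g, start, d, _draw_nadir(config, rng), rng)
        if rng.random() < config.hypo_two_episode_prob:
            # second, shorter excursion; placed left or right of the first
            # with a >= 2-step recovery gap so the runs stay distinct
            d2 = max(1, min(_draw_duration_steps(config, rng) // 2, n))
            nadir2 = _draw_nadir(config, rng)
            left_room = start - d2 - 2
            right_lo = start + d + 2
            right_room = n - right_lo - d2
            if left_room >= 0 and (right_room < 0 or rng.random() < 0.5):
                start2 = int(rng.integers(0, left_room + 1))
                _inject_excursion(g, start2, d2, nadir2, rng)
            elif right_room >= 0:
                start2 = right_lo + int(rng.integers(0, right_room + 1))
                _inject_excursion(g, start2, d2, nadir2, rng)
    return np.clip(g, CLIP_LOW, CLIP_HIGH)


def _inject_excursion(
    g: np.ndarray, start: int, d: int, nadir: float, rng: np.random.Generator
) -> None:
    """Flat-bottomed dip: half-cosine ramps around a plateau near ``nadir``."""
    n = len(g)
    jitter = rng.random(d) * _PLATEAU_JITTER
    g[start:start + d] = nadir + jitter
    g[start + int(np.argmin(jitter))] = nadir  # plateau minimum is the drawn nadir
    for k, w in enumerate(reversed(_RAMP_W)):  # entry ramp: w rises toward plateau
        i = start - (k + 1)
        if i >= 0:
            g[i] = (1.0 - w) * g[i] + w * nadir
    for k, w in enumerate(reversed(_RAMP_W)):  # exit ramp, mirrored
        i = start + d + k
        if i < n:
            g[i] = (1.0 - w) * g[i] + w * nadir


def generate_trace(
    config: SyntheticConfig,
    participant: Participant,
    night_date: dt.date,
    rng: np.random.Generator,
    baseline: float | None = None,
) -> CGMTrace:
    """A single-night CGMTrace (24 readings at :00/:15/:30/:45)."""
    if baseline is None:
        baseline = rng.normal(config.baseline_mean, config.baseline_sd)
    glucose = night_glucose(config, baseline, rng)
    ts = pd.Timestamp(night_date) + pd.to_timedelta(np.arange(24) * 15, unit="m")
    return CGMTrace(
        participant_id=participant.participant_id,
        readings=pd.DataFrame({"timestamp": ts, "glucose": glucose}),
    )


def _covariate(nm: NightMetrics, participant_row: Mapping[str, float], name: str) -> float:
    if name in ("age", "sex_female"):
        return float(participant_row[name])
    if name == "nh39_duration_steps":
        return nm.nh39_duration / metrics.CADENCE_MIN
    if name == "nh30_duration_steps":
        return nm.nh30_duration / metrics.CADENCE_MIN
    val = getattr(nm, name)
    return float(val)


def generate_sleep_score(
    config: SyntheticConfig,
    night_covariates: Mapping[str, float],
    u_i: float,
    rng: np.random.Generator,
) -> int:
    """Draw a 1-5 score from the proportional-odds model.

    P(Y <= k) = logistic(cutpoint_k - eta) with
    eta = sum(beta_j * x_j) + u_i.
    """
    eta = u_i + sum(b * night_covariates[name] for name, b in config.sleep_betas.items())
    kappa = np.asarray(config.sleep_cutpoints, dtype=float)
    cum = 1.0 / (1.0 + np.exp(-(kappa - eta)))
    u = rng.random()
    return int(np.searchsorted(cum, u) + 1)


def _generate_participants(config: SyntheticConfig, rng: np.random.Generator) -> list[Participant]:
    out = []
    for i in range(config.n_participants):
        age = int(np.clip(round(rng.normal(30.6, 8.7)), 18, 65))
        sex = "female" if rng.random() < 18 / 27 else "male"
        gold = int(np.clip(round(rng.normal(2.1, 0.9)), 1, 7))
        dafne = 1 if rng.random() < 0.704 else 2
        treatment = "pump" if rng.random() < 14 / 27 else "MDI"
        out.append(
            Participant(
                participant_id=f"P{i + 1:02d}",
                age=age, sex=sex, gold_score=gold, dafne_score=dafne, treatment=treatment,
            )
        )
    return out


def generate_cohort(
    config: SyntheticConfig,
    seed: int | None = None,
    build_traces: bool = True,
    start_date: dt.date = dt.date(2023, 1, 2),
) -> SyntheticCohort:
    """Generate a full cohort: participants, traces, diary, capillary pairs.

    ``build_traces=False`` skips materializing CGMTrace/capillary frames
    (the ground-truth night table is still produced) for replicate studies
    that only refit the ordinal model.
    """
    if seed is None:
        seed = config.seed
    rngs = _rngs(seed)
    participants = _generate_participants(config, rngs["participants"])

    g_rng, s_rng = rngs["glucose"], rngs["sleep"]
    u_by_pid = {
        p.participant_id: float(s_rng.normal(0.0, config.sigma_u)) for p in participants
    }

    rows: list[dict] = []
    sleep_records: list[SleepRecord] = []
    trace_frames: list[pd.DataFrame] = [] if build_traces else None
    all_glucose: list[np.ndarray] = []
    night_minutes = np.arange(24) * 15.0

    for p in participants:
        baseline = g_rng.normal(config.baseline_mean, config.baseline_sd)
        prow = {"age": p.age, "sex_female": 1.0 if p.sex == "female" else 0.0}
        for j in range(config.nights_per_participant):
            date = start_date + dt.timedelta(days=j)
            glucose = night_glucose(config, baseline, g_rng)
            all_glucose.append(glucose)
            night = NightRecord(
                participant_id=p.participant_id,
                date=date,
                glucose=glucose,
                minutes=night_minutes,
                n_readings=24,
                qc_pass=True,
            )
            nm = metrics.night_summary(night)
            needed = set(config.sleep_betas) | {"age", "sex_female"}
            cov = {name: _covariate(nm, prow, name) for name in needed}
            score = generate_sleep_score(config, cov, u_by_pid[p.participant_id], s_rng)
            sleep_records.append(SleepRecord(p.participant_id, date, score))
            row = nm.to_dict()
            row.update(prow)
            row["sleep_score"] = score
            rows.append(row)
            if build_traces:
                ts = pd.Timestamp(date) + pd.to_timedelta(night_minutes, unit="m")
                trace_frames.append(
                    pd.DataFrame(
                        {"participant_id": p.participant_id, "timestamp": ts, "glucose": glucose}
                    )
                )

    night_table = pd.DataFrame(rows)

    traces = None
    capillary = None
    if build_traces:
        allf = pd.concat(trace_frames, ignore_index=True)
        traces = [
            CGMTrace(pid, grp[["timestamp", "glucose"]].reset_index(drop=True))
            for pid, grp in allf.groupby("participant_id", sort=True)
        ]
        capillary = _generate_capillary(config, allf, rngs["capillary"])

    return SyntheticCohort(
        config=config,
        participants=participants,
        traces=traces,
        sleep_records=sleep_records,
        capillary=capillary,
        night_table=night_table,
        random_intercepts=u_by_pid,
    )


def _generate_capillary(
    config: SyntheticConfig, readings: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Capillary readings as sensor values under multiplicative error.

    capillary = sensor / (1 + e), e ~ N(0, s) with s chosen so
    E|e| = mard_target/100 (|capillary - sensor| / capillary = |e|), i.e.
    s = (mard_target/100) / sqrt(2/pi). Timestamps are offset by a uniform
    0-3 min in either direction, inside the 3-min pairing rule.
    """
    n = min(config.n_capillary_pairs, len(readings))
    idx = rng.choice(len(readings), size=n, replace=False)
    idx.sort()
    sub = readings.iloc[idx]
    s = (config.mard_target / 100.0) / math.sqrt(2.0 / math.pi)
    e = np.clip(rng.normal(0.0, s, size=n), -0.6, 0.6) if s > 0 else np.zeros(n)
    cap = np.clip(sub["glucose"].to_numpy() / (1.0 + e), 1.0, 30.0)
    offset_min = rng.uniform(0.0, 3.0, size=n) * rng.choice([-1.0, 1.0], size=n)
    ts = sub["timestamp"] + pd.to_timedelta(np.round(offset_min * 60), unit="s")
    out = pd.DataFrame(
        {
            "participant_id": sub["participant_id"].to_numpy(),
            "timestamp": ts.to_numpy(),
            "glucose_mmol_l": cap,
        }
    )
    return out.sort_values(["participant_id", "timestamp"], ignore_index=True)


def write_cohort_csvs(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write the four canonical CSVs (cgm, sleep, participants, capillary)."""
    from pathlib import Path
    from noctglu import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cgm": out / "cgm.csv",
        "sleep": out / "sleep.csv",
        "participants": out / "participants.csv",
        "capillary": out / "capillary.csv",
    }
    if cohort.traces is None:
        raise ValueError("cohort was generated with build_traces=False")
    nio.write_cgm_csv(cohort.traces, paths["cgm"])
    nio.write_sleep_csv(cohort.sleep_records, paths["sleep"])
    nio.write_participants_csv(cohort.participants, paths["participants"])
    cap = cohort.capillary.copy()
    cap["timestamp"] = pd.to_datetime(cap["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    cap.to_csv(paths["capillary"], index=False)
    return {k: str(v) for k, v in paths.items()}
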