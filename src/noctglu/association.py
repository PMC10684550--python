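"""Descriptive comparisons, LOWESS inflection analysis, and the pipeline.

Group comparisons follow the study's testing scheme: continuous night
metrics are compared with an independent-samples t test when every
stratum passes a Shapiro-Wilk normality check at alpha = 0.05 and with
Kruskal-Wallis otherwise; proportions use the chi-squared test; awareness
(Gold) scores are correlated with hypoglycemia parameters by Spearman's
rank test. No multiple-testing correction is applied; two-sided p < 0.05
is the nominal significance convention.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from noctglu import accuracy as nacc
from noctglu import metrics as nmetrics
from noctglu import ordinal as nord
from noctglu import smoothing as nsmooth
from noctglu.datatypes import CGMTrace, Participant
from noctglu.io import pair_by_night, participants_frame

logger = logging.getLogger("noctglu")

__all__ = [
    "GroupComparison",
    "compare_nights",
    "correlate_gold",
    "quartile_table",
    "build_night_table",
    "run_pipeline",
]

#: Continuous per-night metrics compared across hypoglycemia strata.
CONTINUOUS_VARS = ("nh39_duration", "nh39_auc", "mean_glucose", "cv", "tir")
#: Shapiro-Wilk gate level for choosing t test vs Kruskal-Wallis.
NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    """One variable's per-stratum summaries and hypothesis test."""

    variable: str
    group_labels: list[str]
    summaries: list[dict]  # per group: n, mean, sd, median, q1, q3
    test: str  # t | kruskal_wallis | chi_squared | spearman
    statistic: float
    p_value: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "group_labels": self.group_labels,
            "summaries": self.summaries,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "note": self.note,
        }


def _summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def compare_nights(
    night_table: pd.DataFrame,
    strat_col: str = "level_class",
    strata: Sequence[str] = ("level1_only", "level2"),
    variables: Sequence[str] = CONTINUOUS_VARS,
) -> list[GroupComparison]:
    """Compare night metrics across hypoglycemia strata.

    Default stratification reproduces the level-1-only vs level-2 night
    comparison (level 1: all hypoglycemic readings in [3.0, 3.9); level
    2: any reading < 3.0 mmol/L). Sleep score and episode-count
    proportions are included alongside the continuous metrics.
    """
    groups = [night_table.loc[night_table[strat_col] == s] for s in strata]
    out: list[GroupComparison] = []

    for var in list(variables) + ["sleep_score"]:
        samples = [g[var].dropna().to_numpy(dtype=float) for g in groups]
        if any(len(s) < 2 for s in samples):
            logger.warning("compare_nights: skipping %r (a stratum has n < 2)", var)
            continue
        normal = all(
            len(s) >= 3 and stats.shapiro(s).pvalue > NORMALITY_ALPHA for s in samples
        )
        if normal and len(samples) == 2:
            res = stats.ttest_ind(*samples)
            test = "t"
        else:
            res = stats.kruskal(*samples)
            test = "kruskal_wallis"
        out.append(
            GroupComparison(
                variable=var,
                group_labels=list(strata),
                summaries=[_summary(s) for s in samples],
                test=test,
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                note=f"normality gate: shapiro per stratum alpha={NORMALITY_ALPHA}, "
                     f"{'passed -> t' if test == 't' else 'failed or >2 strata -> kruskal_wallis'}",
            )
        )

    # episode-frequency proportions (1 vs 2+ episodes/night) by chi-squared
    ep = [g.loc[g["nh39_episodes"] > 0, "nh39_episodes"].to_numpy() for g in groups]
    if all(len(e) >= 2 for e in ep):
        table = np.array([[int((e == 1).sum()), int((e >= 2).sum())] for e in ep])
        if table.sum(axis=0).min() > 0:
            chi2 = stats.chi2_contingency(table, correction=False)
            out.append(
                GroupComparison(
                    variable="nh39_episode_frequency",
                    group_labels=list(strata),
                    summaries=[
                        {"n": int(t.sum()), "one_episode": int(t[0]), "two_plus": int(t[1])}
                        for t in table
                    ],
                    test="chi_squared",
                    statistic=float(chi2.statistic),
                    p_value=float(chi2.pvalue),
                    note="1 vs >=2 episodes per night",
                )
            )
    else:
        logger.warning("compare_nights: skipping episode-frequency chi-squared (n < 2)")
    return out


#: Hypoglycemia parameters correlated with the Gold awareness score.
GOLD_PARAMS = ("nh39_episodes", "nh39_duration", "nh39_auc",
               "nh30_episodes", "nh30_duration", "nh30_auc")


def correlate_gold(
    night_table: pd.DataFrame,
    participants: Iterable[Participant],
    params: Sequence[str] = GOLD_PARAMS,
) -> list[GroupComparison]:
    """Spearman correlation of Gold score with each hypoglycemia parameter.

    Computed across nights (each night carries its participant's Gold
    score). Constant inputs leave rho undefined and are reported as such.
    """
    gold = {p.participant_id: p.gold_score for p in participants}
    g = night_table["participant_id"].map(gold).to_numpy(dtype=float)
    out = []
    for var in params:
        x = night_table[var].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(g == g[0]):
            out.append(
                GroupComparison(
                    variable=var, group_labels=["gold_score"],
                    summaries=[_summary(x)], test="spearman",
                    statistic=float("nan"), p_value=float("nan"),
                    note="rho undefined: constant input",
                )
            )
            continue
        rho, p = stats.spearmanr(g, x)
        out.append(
            GroupComparison(
                variable=var, group_labels=["gold_score"],
                summaries=[_summary(x)], test="spearman",
                statistic=float(rho), p_value=float(p),
            )
        )
    return out


def quartile_table(night_table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) sleep score by duration-quartile bin.

    Bins are the fixed study cuts (0 / 1-45 / 46-90 / 91-150 / >150 min);
    the Q0 bin is exactly the set of nights without hypoglycemia < 3.9.
    """
    rows = []
    for label in ("Q0", "QI", "QII", "QIII", "QIV"):
        sub = night_table.loc[night_table["duration_quartile"] == label, "sleep_score"]
        sub = sub.dropna()
        rows.append(
            {
                "quartile": label,
                "n": int(len(sub)),
                "mean_sleep_score": float(sub.mean()) if len(sub) else float("nan"),
                "sd_sleep_score": float(sub.std(ddof=1)) if len(sub) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def build_night_table(
    traces: Iterable[CGMTrace],
    sleep_records,
    participants: Iterable[Participant],
) -> pd.DataFrame:
    """pair_by_night + night_summary + participant covariates, tidy."""
    pairs = pair_by_night(traces, sleep_records)
    table = nmetrics.nights_table(pairs)
    pf = participants_frame(participants)
    pf["sex_female"] = (pf["sex"] == "female").astype(float)
    table = table.merge(
        pf[["participant_id", "age", "sex_female"]], on="participant_id", how="left"
    )
    return table


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (dt.date, dt.datetime, pd.Timestamp)):
        return obj.isoformat()
    return obj


def _fit_report(model: nord.MixedOrdinalRegression, exposure: str) -> dict:
    b = float(model.coef_[0])
    se = float(model.se_coef_[0])
    z = b / se if se > 0 else float("inf")
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    or_, lo, hi = nord.odds_ratio(model, exposure)
    return {
        "exposure": exposure,
        "beta": b,
        "se": se,
        "or": or_,
        "ci_low": lo,
        "ci_high": hi,
        "p_value": float(p),
        "sigma_u": model.sigma_u_,
        "cutpoints": model.cutpoints_.tolist(),
        "loglik": model.loglik_,
        "converged": model.converged_,
        "n_obs": model.n_obs_,
        "n_groups": model.n_groups_,
    }


def run_pipeline(
    traces: Iterable[CGMTrace],
    sleep_records,
    participants: Iterable[Participant],
    capillary_traces: Iterable[CGMTrace] | None = None,
    *,
    exposures: Sequence[str] | None = None,
    lowess_frac: float = 0.8,
    n_quad: int = 15,
    out_dir=None,
) -> dict:
    """End-to-end analysis: pairing, metrics, comparisons, fits, smoothing.

    Returns a machine-readable results dict; with ``out_dir`` also writes
    nights.csv, results.json, lowess.csv and report.md. Exposures whose
    column is degenerate (e.g. no hypoglycemic nights) are skipped with
    an explicit note, never silently.
    """
    participants = list(participants)
    traces = list(traces)
    table = build_night_table(traces, sleep_records, participants)
    if table.empty:
        raise ValueError("no QC-passing, score-matched nights")

    exposures = list(exposures) if exposures is not None else list(nord.EXPOSURES)
    fits: dict[str, dict] = {}
    for exp in exposures:
        col, factor = nord.EXPOSURES[exp]
        x = table[col].astype(float)
        if x.nunique() < 2:
            fits[exp] = {"skipped": f"exposure {exp!r} is constant in this cohort"}
            logger.warning("pipeline: skipping fit for %s (constant exposure)", exp)
            continue
        model = nord.fit_exposure(table, exp, n_quad=n_quad)
        fits[exp] = _fit_report(model, exp)

    n_total = len(table)
    nh_nights = int(table["nh39_present"].sum())
    comparisons = compare_nights(table) if {"level1_only", "level2"} <= set(
        table["level_class"]
    ) else []
    gold = correlate_gold(table, participants)
    quart = quartile_table(table)

    curve = nsmooth.lowess(
        table["mean_glucose"].to_numpy(), table["sleep_score"].to_numpy(float),
        frac=lowess_frac,
    )

    acc = None
    if capillary_traces is not None:
        acc = nacc.sensor_accuracy_report(capillary_traces, traces)

    results = {
        "n_participants": int(table["participant_id"].nunique()),
        "n_nights": n_total,
        "nh39_nights": nh_nights,
        "nh39_night_rate": nh_nights / n_total,
        "nh30_nights": int(table["nh30_present"].sum()),
        "comparisons": [c.to_dict() for c in comparisons],
        "gold_correlations": [c.to_dict() for c in gold],
        "quartiles": quart.to_dict(orient="records"),
        "fits": fits,
        "lowess": {
            "frac": lowess_frac,
            "x": curve.x.tolist(),
            "y_fitted": curve.y_fitted.tolist(),
            "inflections": curve.inflection_x,
        },
        "accuracy": acc,
    }
    results = _jsonable(results)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "nights.csv", index=False)
        pd.DataFrame(
            {"mean_glucose": curve.x, "sleep_score_fitted": curve.y_fitted}
        ).to_csv(out / "lowess.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
        _write_report(results, out / "report.md")
    return results


def _write_report(results: dict, path) -> None:
    lines = [
        "# Nocturnal hypoglycemia and sleep quality — analysis report",
        "",
        f"- participants: {results['n_participants']}",
        f"- analyzed nights: {results['n_nights']}",
        f"- nights with hypoglycemia < 3.9 mmol/L: {results['nh39_nights']} "
        f"({100 * results['nh39_night_rate']:.1f}%)",
        f"- nights with hypoglycemia < 3.0 mmol/L: {results['nh30_nights']}",
        "",
        "## Adjusted odds ratios (per-exposure mixed ordinal models)",
        "",
        "| exposure | OR | 95% CI | p |",
        "|---|---|---|---|",
    ]
    for exp, f in results["fits"].items():
        if "skipped" in f:
            lines.append(f"| {exp} | — | — | skipped: {f['skipped']} |")
        else:
            lines.append(
                f"| {exp} | {f['or']:.3f} | ({f['ci_low']:.3f}, {f['ci_high']:.3f}) "
                f"| {f['p_value']:.3g} |"
            )
    lines += ["", "## Sleep score by hypoglycemia-duration quartile", ""]
    lines.append("| bin | n | mean score | sd |")
    lines.append("|---|---|---|---|")
    for q in results["quartiles"]:
        mean = q["mean_sleep_score"]
        sd = q["sd_sleep_score"]
        lines.append(
            f"| {q['quartile']} | {q['n']} | "
            f"{'—' if mean is None else format(mean, '.2f')} | "
            f"{'—' if sd is None else format(sd, '.2f')} |"
        )
    infl = ", ".join(f"{v:.2f}" for v in results["lowess"]["inflections"]) or "none"
    lines += ["", f"LOWESS slope-sign inflections (mean glucose, mmol/L): {infl}"]
    if results.get("accuracy"):
        a = results["accuracy"]
        lines += [
            "",
            "## Sensor accuracy",
            "",
            f"- paired readings: {a['n_pairs']}",
            f"- MARD: {a['mard']:.1f}%",
            f"- Clarke zones (%): "
            + ", ".join(f"{z}={a['clarke']['percentages'][z]:.1f}" for z in "ABCDE"),
            f"- Parkes zones (%): "
            + ", ".join(f"{z}={a['parkes_t1']['percentages'][z]:.1f}" for z in "ABCDE"),
        ]
    Path(path).write_text("\n".join(lines) + "\n")
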