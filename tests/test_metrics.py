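"""Night extraction, episode detection, AUC and per-night summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from noctglu import metrics
from noctglu.metrics import (
    auc_below,
    detect_episodes,
    duration_quartile_bin,
    episode_runs,
    extract_night,
    night_summary,
)

from conftest import NIGHT_DATE, make_night, make_trace


def grid_trace(date, n=24, base=6.0, start_minute=0):
    start = pd.Timestamp(date) + pd.Timedelta(minutes=start_minute)
    ts = start + pd.to_timedelta(np.arange(n) * 15, unit="m")
    return make_trace(ts, np.full(n, base))


class TestExtractNight:
    def test_complete_night_passes_qc(self):
        night = extract_night(grid_trace(NIGHT_DATE), NIGHT_DATE)
        assert night.n_readings == 24
        assert night.qc_pass

    @pytest.mark.parametrize("n,expected", [(19, False), (20, True)])
    def test_qc_threshold_is_twenty_readings(self, n, expected):
        night = extract_night(grid_trace(NIGHT_DATE, n=n), NIGHT_DATE)
        assert night.n_readings == n
        assert night.qc_pass is expected

    def test_window_is_half_open_at_0600(self):
        # readings at 05:45 and exactly 06:00: only the former is nocturnal
        ts = [pd.Timestamp(NIGHT_DATE) + pd.Timedelta(minutes=m) for m in (345, 360)]
        night = extract_night(make_trace(ts, [5.0, 5.0]), NIGHT_DATE)
        assert night.n_readings == 1
        assert night.minutes.tolist() == [345.0]

    def test_readings_outside_window_excluded(self):
        # trace spanning the previous evening: nothing before midnight counts
        ts = pd.Timestamp(NIGHT_DATE) + pd.to_timedelta([-60, -15, 0, 15], unit="m")
        night = extract_night(make_trace(ts, [6, 6, 6, 6]), NIGHT_DATE)
        assert night.n_readings == 2

    def test_empty_night_fails_qc_without_error(self):
        night = extract_night(grid_trace(NIGHT_DATE), dt.date(2020, 1, 1))
        assert night.n_readings == 0
        assert not night.qc_pass


class TestEpisodes:
    def test_no_readings_below_gives_no_episodes(self):
        night = make_night([6.0] * 24)
        assert detect_episodes(night, 3.9) == []

    def test_hand_traced_two_episode_night(self):
        # ...4.2, 3.5, 3.7, 4.0, 3.8, 4.1... at 3.9 -> runs of 2 and 1
        g = [4.2, 3.5, 3.7, 4.0, 3.8, 4.1] + [6.0] * 18
        eps = detect_episodes(make_night(g), 3.9)
        assert [(e.n_steps, e.duration) for e in eps] == [(2, 30.0), (1, 15.0)]
        assert eps[0].nadir == 3.5
        assert eps[1].nadir == 3.8

    def test_single_long_dip(self):
        g = [6.0] * 7 + [3.0] * 10 + [6.0] * 7
        eps = detect_episodes(make_night(g), 3.9)
        assert len(eps) == 1
        assert eps[0].duration == 150.0

    def test_gap_breaks_a_run(self):
        # below-threshold readings at 0, 15 and 45 min: the 30-min hole splits them
        night = make_night([3.0, 3.0, 3.0], minutes=[0.0, 15.0, 45.0])
        night.qc_pass = True  # bypass QC to probe run logic directly
        eps = detect_episodes(night, 3.9)
        assert [e.n_steps for e in eps] == [2, 1]

    def test_reading_exactly_at_threshold_not_hypoglycemic(self):
        night = make_night([3.9] * 24)
        assert detect_episodes(night, 3.9) == []

    def test_qc_failed_night_raises(self):
        with pytest.raises(ValueError, match="failed QC"):
            detect_episodes(make_night([3.0] * 10), 3.9)

    def test_episode_invariants_on_random_nights(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            g = rng.uniform(2.0, 12.0, 24)
            night = make_night(g)
            for thr in (3.9, 3.0):
                for e in detect_episodes(night, thr):
                    assert e.n_steps >= 1
                    assert e.duration >= 15.0
                    assert e.nadir < thr


class TestAuc:
    def test_zero_when_nothing_below(self):
        assert auc_below(make_night([6.0] * 24), 3.9) == 0.0

    def test_hand_computed_value(self):
        # readings 3.5 and 3.7 below 3.9 -> (0.4 + 0.2) * 15 = 9.0
        g = [6.0] * 22 + [3.5, 3.7]
        assert auc_below(make_night(g), 3.9) == pytest.approx(9.0)

    def test_literal_resummation_on_random_nights(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            g = rng.uniform(1.5, 12.0, 24)
            night = make_night(g)
            for thr in (3.9, 3.0):
                expected = sum((thr - v) * 15.0 for v in g if v < thr)
                assert auc_below(night, thr) == pytest.approx(expected, rel=1e-12)


def _bruteforce_episodes(glucose, minutes, threshold):
    """Independent O(n^2) oracle: test every contiguous index range."""
    n = len(glucose)
    below = [g < threshold for g in glucose]
    adjacent = [minutes[i + 1] - minutes[i] <= 15.0 + 1e-9 for i in range(n - 1)]
    out = []
    for i in range(n):
        for j in range(i, n):
            if not all(below[i : j + 1]):
                continue
            if not all(adjacent[i:j]):
                continue
            # maximality on both sides
            if i > 0 and below[i - 1] and adjacent[i - 1]:
                continue
            if j < n - 1 and below[j + 1] and adjacent[j]:
                continue
            out.append((i, j - i + 1, min(glucose[i : j + 1])))
    return out


@pytest.fixture(scope="module")
def random_nights():
    rng = np.random.default_rng(99)
    nights = []
    for _ in range(1000):
        n = rng.integers(20, 25)
        g = np.round(rng.uniform(1.2, 13.0, n), 1)
        # random gaps: drop the regular grid occasionally
        minutes = np.sort(rng.choice(np.arange(24) * 15.0, size=n, replace=False))
        nights.append(make_night(g, minutes=minutes))
    return nights


class TestNightSummaryProperties:
    def test_episodes_match_bruteforce_oracle(self, random_nights):
        for night in random_nights:
            for thr in (3.9, 3.0):
                fast = episode_runs(night.glucose, thr, night.minutes)
                slow = _bruteforce_episodes(
                    night.glucose.tolist(), night.minutes.tolist(), thr
                )
                assert fast == slow

    def test_time_partition_sums_to_100(self, random_nights):
        for night in random_nights:
            nm = night_summary(night)
            below = 100.0 * np.sum(night.glucose < 3.9) / night.n_readings
            above = 100.0 * np.sum(night.glucose > 10.0) / night.n_readings
            assert below + nm.tir + above == pytest.approx(100.0, abs=1e-9)

    def test_level2_metrics_bounded_by_level1(self, random_nights):
        for night in random_nights:
            nm = night_summary(night)
            assert nm.nh30_duration <= nm.nh39_duration
            assert nm.nh30_auc <= nm.nh39_auc
            if nm.level_class == "level2":
                assert nm.nh39_present

    def test_episode_durations_sum_to_total_duration(self, random_nights):
        for night in random_nights:
            nm = night_summary(night)
            eps = detect_episodes(night, 3.9)
            assert sum(e.duration for e in eps) == pytest.approx(nm.nh39_duration)


class TestNightSummaryValues:
    def test_constant_glucose(self):
        nm = night_summary(make_night([5.0] * 24))
        assert nm.mean_glucose == 5.0
        assert nm.cv == 0.0
        assert nm.tir == 100.0
        assert nm.level_class == "none"
        assert nm.duration_quartile == "Q0"

    def test_level_classification_by_nadir(self):
        g1 = [6.0] * 20 + [3.4] * 4
        g2 = [6.0] * 20 + [2.5] * 4
        assert night_summary(make_night(g1)).level_class == "level1_only"
        assert night_summary(make_night(g2)).level_class == "level2"

    def test_cv_is_sample_sd_over_mean(self):
        g = np.array([4.0, 5.0, 6.0, 7.0] * 6)
        nm = night_summary(make_night(g))
        assert nm.cv == pytest.approx(100 * g.std(ddof=1) / g.mean())

    @pytest.mark.parametrize(
        "duration,label",
        [(0, "Q0"), (15, "QI"), (45, "QI"), (46, "QII"), (90, "QII"),
         (91, "QIII"), (150, "QIII"), (165, "QIV"), (400, "QIV")],
    )
    def test_duration_quartile_bins(self, duration, label):
        assert duration_quartile_bin(duration) == label

    def test_tir_bounds_inclusive(self):
        # 3.9 and 10.0 are in range by convention
        g = [3.9, 10.0] * 12
        assert night_summary(make_night(g)).tir == 100.0
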