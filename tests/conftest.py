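import datetime as dt

import numpy as np
import pandas as pd
import pytest

from noctglu.datatypes import CGMTrace
from noctglu.metrics import NightRecord
from noctglu.simulate import SyntheticConfig, generate_cohort

NIGHT_DATE = dt.date(2023, 3, 10)


def make_night(glucose, minutes=None, participant_id="P01", date=NIGHT_DATE):
    """NightRecord from a raw glucose list (default: gap-free 15-min grid)."""
    g = np.asarray(glucose, dtype=float)
    if minutes is None:
        minutes = np.arange(len(g)) * 15.0
    else:
        minutes = np.asarray(minutes, dtype=float)
    return NightRecord(
        participant_id=participant_id,
        date=date,
        glucose=g,
        minutes=minutes,
        n_readings=len(g),
        qc_pass=len(g) >= 20,
    )


def make_trace(timestamps, glucose, participant_id="P01"):
    return CGMTrace(
        participant_id=participant_id,
        readings=pd.DataFrame(
            {"timestamp": pd.to_datetime(timestamps), "glucose": glucose}
        ),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant cohort with traces, diary and capillary pairs."""
    cfg = SyntheticConfig(n_participants=12, nights_per_participant=14,
                          n_capillary_pairs=300)
    return generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def default_cohort_table():
    """Ground-truth night table of a default-scale cohort (27 x 28)."""
    return generate_cohort(SyntheticConfig(), seed=11, build_traces=False).night_table
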