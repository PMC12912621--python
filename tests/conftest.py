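import numpy as np
import pandas as pd
import pytest

from agmi.discordance import add_discordance
from agmi.io import CgmTrace
from agmi.simulate import SyntheticConfig, simulate_visits, visits_to_pairs


def make_trace(subject_id="A", start="2021-01-01", days=30, interval=5,
               glucose=150.0, per_day=None):
    """Constant-glucose trace with ``per_day`` readings on each day
    (defaults to full coverage for the interval)."""
    expected = 1440 // interval
    per_day = expected if per_day is None else per_day
    ts = []
    base = pd.Timestamp(start)
    for d in range(days):
        day = base + pd.Timedelta(days=d)
        ts.extend(day + pd.Timedelta(minutes=interval * k) for k in range(per_day))
    data = pd.DataFrame({"timestamp": pd.DatetimeIndex(ts),
                         "glucose": float(glucose)})
    return CgmTrace(subject_id, data, interval)


def pairs_from_records(records):
    """Pair table from (subject, index, date, hba1c, mean_glucose) tuples."""
    rows = []
    for sid, idx, date, hba1c, mg in records:
        date = pd.Timestamp(date)
        rows.append({"subject_id": sid, "pair_index": idx, "hba1c_date": date,
                     "hba1c": hba1c, "window_start": date - pd.Timedelta(days=60),
                     "window_end": date, "active_day_count": 60,
                     "mean_glucose": mg, "n_readings": 5760,
                     "days_since_baseline": np.nan})
    df = pd.DataFrame(rows).sort_values(["subject_id", "pair_index"])
    base = df.groupby("subject_id")["hba1c_date"].transform("first")
    df["days_since_baseline"] = (df["hba1c_date"] - base).dt.days.astype(float)
    return add_discordance(df.reset_index(drop=True))


@pytest.fixture(scope="session")
def visit_pairs():
    """Mid-size visit-level synthetic cohort, discordance-annotated."""
    cfg = SyntheticConfig(seed=424, n_subjects=300)
    return add_discordance(visits_to_pairs(simulate_visits(cfg)))


@pytest.fixture(scope="session")
def model_rows(visit_pairs):
    from agmi.model import make_model_rows
    return make_model_rows(visit_pairs)
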