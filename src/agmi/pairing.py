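"""Join laboratory HbA1c draws to their preceding CGM windows.

Each HbA1c value is evaluated against the subject's cleaned CGM trace over
the half-open 60-day window ``[draw_date - 60 d, draw_date)``. A pair is
kept when the window contains at least 14 active wear days; subjects must
contribute at least two such pairs to enter the longitudinal analysis.

Pairs are carried as a pandas DataFrame, one row per pair, with columns

    subject_id, pair_index, hba1c_date, hba1c, window_start, window_end,
    active_day_count, mean_glucose, n_readings, days_since_baseline

(the discordance module later appends ``gmi``, ``discordance``, ``group``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CgmTrace, DEFAULT_COVERAGE_THRESHOLD, active_days

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_DAYS = 60
DEFAULT_MIN_ACTIVE_DAYS = 14
DEFAULT_MIN_PAIRS = 2

PAIR_COLUMNS = [
    "subject_id", "pair_index", "hba1c_date", "hba1c", "window_start",
    "window_end", "active_day_count", "mean_glucose", "n_readings",
    "days_since_baseline",
]


def _empty_pairs() -> pd.DataFrame:
    df = pd.DataFrame(columns=PAIR_COLUMNS)
    return df.astype({"pair_index": int, "active_day_count": int, "n_readings": int,
                      "hba1c": float, "mean_glucose": float, "days_since_baseline": float},
                     errors="ignore")


def build_pairs(traces: dict[str, CgmTrace], hba1c_records: pd.DataFrame,
                window_days: int = DEFAULT_WINDOW_DAYS,
                min_active_days: int = DEFAULT_MIN_ACTIVE_DAYS,
                coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> pd.DataFrame:
    """Build eligible HbA1c-CGM pairs.

    For each HbA1c record the window ``[date - window_days, date)`` is
    evaluated on that subject's trace; the pair is emitted iff its active-day
    count reaches ``min_active_days``. ``mean_glucose`` is the unweighted
    mean of all retained readings in the window. Duplicate draw dates within
    a subject keep the first record; subjects absent from ``traces`` are
    skipped with a log message.
    """
    if hba1c_records.empty:
        return _empty_pairs()
    records = hba1c_records.drop_duplicates(subset=["subject_id", "date"], keep="first")
    if len(records) < len(hba1c_records):
        logger.info("dropped %d duplicate-date HbA1c records",
                    len(hba1c_records) - len(records))
    rows = []
    for sid, grp in records.groupby("subject_id", sort=True):
        trace = traces.get(sid)
        if trace is None:
            logger.info("subject %s has HbA1c records but no CGM trace; skipped", sid)
            continue
        ts = trace.data["timestamp"].to_numpy()
        glucose = trace.data["glucose"].to_numpy()
        for rec in grp.sort_values("date", kind="stable").itertuples(index=False):
            end = pd.Timestamp(rec.date)
            start = end - pd.Timedelta(days=window_days)
            n_active = active_days(trace, start, end, coverage_threshold)
            if n_active < min_active_days:
                continue
            mask = (ts >= np.datetime64(start)) & (ts < np.datetime64(end))
            g = glucose[mask]
            rows.append({
                "subject_id": sid,
                "pair_index": -1,  # assigned below
                "hba1c_date": end,
                "hba1c": float(rec.hba1c),
                "window_start": start,
                "window_end": end,
                "active_day_count": n_active,
                "mean_glucose": float(g.mean()),
                "n_readings": int(mask.sum()),
                "days_since_baseline": np.nan,
            })
    if not rows:
        return _empty_pairs()
    pairs = pd.DataFrame(rows)
    return _renumber(pairs)


def _renumber(pairs: pd.DataFrame) -> pd.DataFrame:
    """Re-assign chronological pair indices and days-since-baseline."""
    pairs = pairs.sort_values(["subject_id", "hba1c_date"], kind="stable").reset_index(drop=True)
    pairs["pair_index"] = pairs.groupby("subject_id").cumcount()
    base = pairs.groupby("subject_id")["hba1c_date"].transform("first")
    pairs["days_since_baseline"] = (pairs["hba1c_date"] - base).dt.total_seconds() / 86400.0
    return pairs


def filter_eligible_subjects(pairs: pd.DataFrame,
                             min_pairs: int = DEFAULT_MIN_PAIRS) -> pd.DataFrame:
    """Keep subjects contributing at least ``min_pairs`` pairs; renumber."""
    if pairs.empty:
        return pairs.copy()
    counts = pairs.groupby("subject_id")["pair_index"].size()
    keep = counts.index[counts >= min_pairs]
    out = pairs[pairs["subject_id"].isin(keep)].copy()
    if out.empty:
        return _empty_pairs()
    return _renumber(out)


def cohort_summary(pairs: pd.DataFrame) -> dict:
    """Descriptive statistics of an eligible-pair table.

    Returns subject/pair counts, mean +/- SD of HbA1c and window mean
    glucose, median (IQR) active CGM days per pair, and median (IQR) gap in
    days between a subject's consecutive pairs.
    """
    if pairs.empty:
        raise ValueError("cohort_summary requires a non-empty pair table")
    gaps = (pairs.sort_values(["subject_id", "pair_index"])
            .groupby("subject_id")["hba1c_date"].diff().dropna()
            .dt.total_seconds() / 86400.0)
    days = pairs["active_day_count"]

    def med_iqr(x):
        if len(x) == 0:
            return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
        q1, med, q3 = np.percentile(np.asarray(x, dtype=float), [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}

    return {
        "n_subjects": int(pairs["subject_id"].nunique()),
        "n_pairs": int(len(pairs)),
        "hba1c_mean": float(pairs["hba1c"].mean()),
        "hba1c_sd": float(pairs["hba1c"].std(ddof=1)) if len(pairs) > 1 else 0.0,
        "mean_glucose_mean": float(pairs["mean_glucose"].mean()),
        "mean_glucose_sd": float(pairs["mean_glucose"].std(ddof=1)) if len(pairs) > 1 else 0.0,
        "cgm_days_per_pair": med_iqr(days),
        "inter_pair_gap_days": med_iqr(gaps),
    }
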