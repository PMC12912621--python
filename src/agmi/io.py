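"""Data model, CSV I/O and quality control for CGM traces and HbA1c records.

A :class:`CgmTrace` is one subject's interstitial-glucose time series at its
native 5- or 15-minute sampling. Cleaning removes duplicate timestamps and
physiologically implausible readings (outside [40, 400] mg/dL, bounds
retained) and never interpolates across gaps: sensor dropout simply leaves
missing samples, which the active-wear accounting then sees.

HbA1c records are laboratory values in % NGSP, one dated row per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .units import mmoll_to_mgdl

#: plausibility band for retained glucose readings, mg/dL (inclusive)
GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 400.0

#: default fraction of a day's expected samples required for an "active" day
DEFAULT_COVERAGE_THRESHOLD = 0.7

CGM_COLUMNS = {"subject_id": "subject_id", "timestamp": "timestamp", "glucose": "glucose"}
HBA1C_COLUMNS = {"subject_id": "subject_id", "date": "date", "hba1c_percent": "hba1c_percent"}


@dataclass(frozen=True)
class QcReport:
    """Per-trace cleaning ledger; counts partition the raw input rows."""

    raw: int = 0
    duplicates_removed: int = 0
    out_of_range_removed: int = 0
    retained: int = 0

    def as_dict(self) -> dict:
        return {
            "raw": self.raw,
            "duplicates_removed": self.duplicates_removed,
            "out_of_range_removed": self.out_of_range_removed,
            "retained": self.retained,
        }


@dataclass
class CgmTrace:
    """One subject's CGM series.

    Attributes
    ----------
    subject_id : str
    data : pandas.DataFrame
        Columns ``timestamp`` (datetime64) and ``glucose`` (mg/dL), sorted by
        timestamp.
    sampling_interval : int
        Native sampling interval in minutes (5 or 15).
    qc : QcReport or None
        Populated by :func:`clean_trace`; ``None`` on an uncleaned trace.
    """

    subject_id: str
    data: pd.DataFrame
    sampling_interval: int = 5
    qc: QcReport | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def expected_per_day(self) -> int:
        return 1440 // self.sampling_interval


class FormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


def _require_columns(df: pd.DataFrame, names, path) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_cgm_csv(path, column_map=None, glucose_unit: str = "mg/dL",
                 sampling_interval: int = 5) -> dict[str, CgmTrace]:
    """Read a CGM CSV into per-subject traces (uncleaned, time-sorted).

    Parameters
    ----------
    path : str or Path
        CSV with subject, timestamp and glucose columns.
    column_map : dict, optional
        Maps logical names (``subject_id``, ``timestamp``, ``glucose``) to the
        file's column names; defaults to the logical names themselves.
    glucose_unit : {"mg/dL", "mmol/L"}
        Unit of the glucose column; mmol/L values are converted on read.
    sampling_interval : int
        Native sampling interval in minutes, recorded on every trace.

    Returns
    -------
    dict mapping subject_id -> CgmTrace
    """
    cols = dict(CGM_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return {}
    _require_columns(df, cols.values(), path)
    if df.empty:
        return {}
    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise FormatError(
            f"{path}: unparseable timestamp {df[cols['timestamp']].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    glucose = pd.to_numeric(df[cols["glucose"]], errors="coerce").astype(float)
    if glucose_unit == "mmol/L":
        glucose = mmoll_to_mgdl(glucose.to_numpy())
        glucose = pd.Series(glucose, index=df.index)
    elif glucose_unit != "mg/dL":
        raise ValueError(f"unknown glucose unit {glucose_unit!r}")
    tidy = pd.DataFrame({
        "subject_id": df[cols["subject_id"]].astype(str),
        "timestamp": ts,
        "glucose": glucose,
    })
    traces = {}
    for sid, grp in tidy.groupby("subject_id", sort=True):
        g = grp.sort_values("timestamp", kind="stable")[["timestamp", "glucose"]]
        traces[sid] = CgmTrace(sid, g.reset_index(drop=True), sampling_interval)
    return traces


def read_hba1c_csv(path, column_map=None) -> pd.DataFrame:
    """Read laboratory HbA1c records.

    Returns a DataFrame with columns ``subject_id`` (str), ``date``
    (datetime64) and ``hba1c`` (% NGSP), sorted by subject then date,
    preserving file order within ties.
    """
    cols = dict(HBA1C_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["subject_id", "date", "hba1c"])
    _require_columns(df, cols.values(), path)
    if df.empty:
        return pd.DataFrame(columns=["subject_id", "date", "hba1c"])
    dates = pd.to_datetime(df[cols["date"]], errors="coerce", format="ISO8601")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna())[0])
        raise FormatError(
            f"{path}: unparseable date {df[cols['date']].iloc[row]!r} at data row {row + 1}"
        )
    out = pd.DataFrame({
        "subject_id": df[cols["subject_id"]].astype(str),
        "date": dates,
        "hba1c": pd.to_numeric(df[cols["hba1c_percent"]]).astype(float),
    })
    bad = ~np.isfinite(out["hba1c"]) | (out["hba1c"] <= 0)
    if bad.any():
        raise FormatError(f"{path}: non-positive or non-finite HbA1c at data row "
                          f"{int(np.flatnonzero(bad)[0]) + 1}")
    return out.sort_values(["subject_id", "date"], kind="stable").reset_index(drop=True)


def clean_trace(trace: CgmTrace) -> CgmTrace:
    """Apply the preprocessing rules to one trace.

    Duplicate timestamps keep the first occurrence; readings below 40 or
    above 400 mg/dL are dropped (40 and 400 themselves are retained); no
    interpolation or gap filling is performed. Cleaning is idempotent and the
    QC counts partition the input rows.
    """
    df = trace.data
    raw = len(df)
    dedup = df.drop_duplicates(subset="timestamp", keep="first")
    n_dup = raw - len(dedup)
    in_range = (dedup["glucose"] >= GLUCOSE_MIN) & (dedup["glucose"] <= GLUCOSE_MAX)
    kept = dedup.loc[in_range].reset_index(drop=True)
    qc = QcReport(
        raw=raw,
        duplicates_removed=n_dup,
        out_of_range_removed=int((~in_range).sum()),
        retained=len(kept),
    )
    return replace(trace, data=kept, qc=qc)


def active_days(trace: CgmTrace, window_start, window_end,
                coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> int:
    """Count days of active CGM wear inside ``[window_start, window_end)``.

    A calendar day is active when its retained-reading count reaches
    ``coverage_threshold`` x the day's expected sample count (288 at 5-minute
    sampling, 96 at 15-minute).
    """
    window_start = pd.Timestamp(window_start)
    window_end = pd.Timestamp(window_end)
    if not window_start < window_end:
        raise ValueError("window_start must precede window_end")
    ts = trace.data["timestamp"]
    sel = ts[(ts >= window_start) & (ts < window_end)]
    if sel.empty:
        return 0
    per_day = sel.dt.normalize().value_counts()
    needed = coverage_threshold * trace.expected_per_day
    return int((per_day >= needed).sum())
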