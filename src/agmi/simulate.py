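"""Synthetic cohort generator.

Emulates the statistical structure the discordance analysis assumes, so the
whole pipeline runs and can be validated with no external data:

* per-subject habitual mean glucose ~ Normal(163, 31) mg/dL truncated to
  [70, 300];
* laboratory visits 2-5 per subject with lognormal inter-visit gaps
  (median 126 days); visit frequency is mildly coupled to the subject's
  glycation-offset magnitude (poorly matched subjects are re-tested
  sooner), the standard clinical scheduling pattern;
* each visit's 60-day window has a true mean glucose (the habitual mean
  plus a per-visit deviation), and observed HbA1c = GMI(window mean)
  + persistent subject offset delta + visit-level transient offset eps
  + laboratory assay noise.
  delta ~ Normal(0, sigma_persistent) encodes stable high/low glycators;
  eps starts at SD sigma_transient and decays along an AR(1) with
  timescale tau_transient toward a smaller stationary floor
  (transient_floor x sigma_transient), so discordance magnitude attenuates
  with time from baseline;
* CGM traces: subject mean + diurnal sinusoid + mean-reverting (AR(1))
  noise at 5- or 15-minute sampling, clipped to [40, 400] mg/dL, with
  sensor wear/dropout as alternating exponential-duration segments.

Two fidelities are exposed: :func:`simulate_cohort` emits full CGM traces
plus HbA1c CSV-ready tables; :func:`simulate_visits` emits the visit-level
quantities only (same offset model, true window means, no trace synthesis)
for cheap replicated studies of the downstream statistics.

All randomness flows from the single ``seed`` in :class:`SyntheticConfig`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.signal import lfilter

from .discordance import gmi_from_mean
from .io import CgmTrace
from .model import GmiAdjuster

#: mean absolute deviation of a standard normal (centers the gap coupling)
_MEAN_ABS_NORMAL = float(np.sqrt(2.0 / np.pi))


class SyntheticConfig(BaseModel):
    """Generator parameters; defaults define the reference study conditions."""

    n_subjects: int = Field(477, ge=1)
    visits_min: int = Field(2, ge=1)
    visits_max: int = Field(5, ge=1)

    # visit schedule
    gap_median_days: float = Field(126.0, gt=0)
    gap_log_sd: float = Field(0.58, ge=0)
    gap_offset_coupling: float = Field(0.22, ge=0)

    # glucose process
    mean_glucose_mean: float = Field(163.0, gt=0)
    mean_glucose_sd: float = Field(31.0, ge=0)
    mean_glucose_bounds: tuple[float, float] = (70.0, 300.0)
    sigma_window_mean: float = Field(15.0, ge=0)
    diurnal_amplitude: float = Field(25.0, ge=0)
    noise_sd: float = Field(20.0, ge=0)
    noise_tau_minutes: float = Field(60.0, gt=0)
    sampling_interval: int = Field(15)

    # sensor wear / dropout
    wear_mean_days: float = Field(25.0, gt=0)
    dropout_mean_days: float = Field(4.0, ge=0)

    # glycation offsets (HbA1c % scale)
    sigma_persistent: float = Field(0.40, ge=0)
    sigma_transient: float = Field(0.25, ge=0)
    tau_transient: float = Field(180.0, gt=0)
    transient_floor: float = Field(0.4, ge=0, le=1)
    sigma_lab: float = Field(0.10, ge=0)

    # inert demographic covariates
    age_mean: float = 40.0
    age_sd: float = 16.0
    female_fraction: float = Field(0.57, ge=0, le=1)

    start_date: str = "2020-01-01"
    seed: int

    @model_validator(mode="after")
    def _check(self):
        if self.sampling_interval not in (5, 15):
            raise ValueError("sampling_interval must be 5 or 15 minutes")
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max must be >= visits_min")
        lo, hi = self.mean_glucose_bounds
        if not lo < hi:
            raise ValueError("mean_glucose_bounds must be increasing")
        return self


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_visits(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Visit-level ground truth: schedule, offsets and observed HbA1c.

    Returns one row per visit with columns ``subject_id, visit_index, date,
    days_since_baseline, true_mean_glucose, window_mean_glucose, true_gmi,
    delta, eps, lab_noise, true_discordance, hba1c, age, sex``.
    ``window_mean_glucose`` is the 60-day window's true mean (the subject's
    habitual mean plus a per-visit deviation of SD ``sigma_window_mean``),
    ``true_gmi`` derives from it, and ``true_discordance`` is
    ``delta + eps + lab_noise``, i.e. exactly ``hba1c - true_gmi``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    lo, hi = config.mean_glucose_bounds
    mean_g = _truncated_normal(rng, config.mean_glucose_mean, config.mean_glucose_sd,
                               lo, hi, n)
    delta = rng.normal(0.0, config.sigma_persistent, n)
    n_visits = rng.integers(config.visits_min, config.visits_max + 1, n)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 90)
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female
    start = pd.Timestamp(config.start_date)
    # baseline draw sits 60-120 days in, so the first CGM window fits
    base_offset = rng.uniform(60.0, 120.0, n)

    rows = []
    sp = config.sigma_persistent
    st = config.sigma_transient
    for i in range(n):
        k = int(n_visits[i])
        if sp > 0 and config.gap_offset_coupling > 0:
            shift = config.gap_offset_coupling * (abs(delta[i]) / sp - _MEAN_ABS_NORMAL)
        else:
            shift = 0.0
        mu = np.log(config.gap_median_days) - shift
        gaps = np.exp(rng.normal(mu, config.gap_log_sd, k - 1)) if k > 1 else np.array([])
        t_days = np.concatenate([[0.0], np.cumsum(gaps)])
        eps = np.empty(k)
        eps[0] = rng.normal(0.0, st)
        for j in range(1, k):
            rho = np.exp(-gaps[j - 1] / config.tau_transient)
            inn_sd = config.transient_floor * st * np.sqrt(max(0.0, 1.0 - rho ** 2))
            eps[j] = rho * eps[j - 1] + rng.normal(0.0, inn_sd)
        lab = rng.normal(0.0, config.sigma_lab, k)
        wmean = np.clip(mean_g[i] + rng.normal(0.0, config.sigma_window_mean, k),
                        lo, hi)
        for j in range(k):
            d_true = delta[i] + eps[j] + lab[j]
            true_gmi = gmi_from_mean(wmean[j])
            rows.append({
                "subject_id": f"S{i:05d}",
                "visit_index": j,
                "date": start + pd.Timedelta(days=float(base_offset[i] + t_days[j])),
                "days_since_baseline": float(t_days[j]),
                "true_mean_glucose": float(mean_g[i]),
                "window_mean_glucose": float(wmean[j]),
                "true_gmi": float(true_gmi),
                "delta": float(delta[i]),
                "eps": float(eps[j]),
                "lab_noise": float(lab[j]),
                "true_discordance": float(d_true),
                "hba1c": float(true_gmi + d_true),
                "age": float(age[i]),
                "sex": int(sex[i]),
            })
    df = pd.DataFrame(rows)
    df["date"] = df["date"].dt.floor("D")
    return df


def visits_to_pairs(visits: pd.DataFrame, window_days: int = 60) -> pd.DataFrame:
    """Cast visit-level ground truth into the pair-table layout.

    Uses each visit's true window mean (ideal full wear), so downstream
    discordance equals the generative ``delta + eps + lab_noise``. Handy
    for replicated studies of the longitudinal statistics without trace
    synthesis.
    """
    out = pd.DataFrame({
        "subject_id": visits["subject_id"],
        "pair_index": visits["visit_index"],
        "hba1c_date": visits["date"],
        "hba1c": visits["hba1c"],
        "window_start": visits["date"] - pd.Timedelta(days=window_days),
        "window_end": visits["date"],
        "active_day_count": window_days,
        "mean_glucose": visits["window_mean_glucose"],
        "n_readings": 0,
        "days_since_baseline": visits["days_since_baseline"],
        "age": visits["age"],
        "sex": visits["sex"],
    })
    return out.reset_index(drop=True)


def sample_baseline_discordance(config: SyntheticConfig, n: int,
                                seed: int | None = None) -> np.ndarray:
    """Draw ``n`` first-visit discordance values from the generative marginal.

    At baseline the marginal is Normal with variance
    ``sigma_persistent^2 + sigma_transient^2 + sigma_lab^2``; used for
    calibration checks of the phenotype prevalence.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sd = float(np.sqrt(config.sigma_persistent ** 2 + config.sigma_transient ** 2
                       + config.sigma_lab ** 2))
    return rng.normal(0.0, sd, n)


def simulate_trace(subject_id: str, mean_glucose, segments,
                   config: SyntheticConfig, rng: np.random.Generator) -> CgmTrace:
    """Simulate one subject's CGM trace over the given wear segments.

    ``segments`` is an iterable of ``(start, end)`` timestamps, or
    ``(start, end, level)`` to override ``mean_glucose`` per segment;
    samples fall on the sampling grid inside each segment. Glucose is the
    segment level plus a diurnal sinusoid (peak mid-afternoon) plus
    mean-reverting AR(1) noise, clipped to the sensor's [40, 400] mg/dL
    range.
    """
    step = pd.Timedelta(minutes=config.sampling_interval)
    rho = float(np.exp(-config.sampling_interval / config.noise_tau_minutes))
    inn_sd = config.noise_sd * np.sqrt(1.0 - rho ** 2)
    all_ts, all_g = [], []
    for seg in segments:
        seg_start, seg_end = seg[0], seg[1]
        level = float(seg[2]) if len(seg) > 2 else float(mean_glucose)
        ts = pd.date_range(seg_start, seg_end, freq=step, inclusive="left")
        if len(ts) == 0:
            continue
        hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
        diurnal = config.diurnal_amplitude * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
        noise0 = rng.normal(0.0, config.noise_sd)
        if len(ts) > 1:
            innov = rng.normal(0.0, inn_sd, len(ts) - 1)
            tail, _ = lfilter([1.0], [1.0, -rho], innov, zi=[rho * noise0])
            noise = np.concatenate([[noise0], tail])
        else:
            noise = np.array([noise0])
        all_ts.append(ts)
        all_g.append(np.clip(level + diurnal + noise, 40.0, 400.0))
    if all_ts:
        data = pd.DataFrame({
            "timestamp": pd.DatetimeIndex(np.concatenate([t.to_numpy() for t in all_ts])),
            "glucose": np.concatenate(all_g),
        }).sort_values("timestamp", kind="stable").reset_index(drop=True)
    else:
        data = pd.DataFrame({"timestamp": pd.DatetimeIndex([]), "glucose": []})
    return CgmTrace(subject_id, data, config.sampling_interval)


def _wear_segments(span_start, span_end, config: SyntheticConfig,
                   rng: np.random.Generator):
    """Alternating wear/dropout segments with exponential durations."""
    if config.dropout_mean_days == 0:
        return [(span_start, span_end)]
    segments = []
    t = span_start
    wearing = rng.random() < (config.wear_mean_days
                              / (config.wear_mean_days + config.dropout_mean_days))
    while t < span_end:
        mean = config.wear_mean_days if wearing else config.dropout_mean_days
        dur = pd.Timedelta(days=float(rng.exponential(mean)))
        if wearing:
            segments.append((t, min(t + dur, span_end)))
        t = t + dur
        wearing = not wearing
    return segments


def simulate_cohort(config: SyntheticConfig,
                    window_days: int = 60) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Full-fidelity cohort: CGM traces, HbA1c records and ground truth.

    Returns ``(traces, hba1c_records, ground_truth)`` where ``traces`` maps
    subject_id -> :class:`~agmi.io.CgmTrace`, ``hba1c_records`` matches the
    HbA1c CSV schema, and ``ground_truth`` is the :func:`simulate_visits`
    table. Byte-identical outputs for identical config + seed.
    """
    visits = simulate_visits(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    traces = {}
    for sid, grp in visits.groupby("subject_id", sort=True):
        span_start = grp["date"].min() - pd.Timedelta(days=window_days)
        span_end = grp["date"].max()
        # glucose level is a step function: each inter-visit stretch runs at
        # the *next* visit's true window mean, so a 60-day window that fits
        # inside its stretch realizes that mean exactly (up to sensor noise)
        bounds = [span_start] + list(grp["date"])
        levels = list(grp["window_mean_glucose"])
        pieces = []
        for wear_start, wear_end in _wear_segments(span_start, span_end, config, rng):
            for j in range(len(levels)):
                lo_b, hi_b = bounds[j], bounds[j + 1]
                s, e = max(wear_start, lo_b), min(wear_end, hi_b)
                if s < e:
                    pieces.append((s, e, levels[j]))
        traces[sid] = simulate_trace(sid, float(grp["true_mean_glucose"].iloc[0]),
                                     pieces, config, rng)
    records = visits[["subject_id", "date", "hba1c"]].copy()
    return traces, records, visits


def recovery_report(ground_truth: pd.DataFrame, fitted_model: GmiAdjuster,
                    pairs: pd.DataFrame, discordance_tol: float = 0.15,
                    beta1_z: float = 4.0) -> dict:
    """Check that the pipeline recovers the generator's ground truth.

    Matches pipeline pairs to ground-truth visits on subject and date and
    reports (a) the error between pipeline discordance and the generative
    ``delta + eps + lab_noise`` (driven by window-sampling error), (b) group
    label agreement against thresholded truth, and (c) whether the fitted
    GMI coefficient sits within ``beta1_z`` standard errors of its
    generative value 1 and the prior-discordance coefficient is positive.
    """
    gt = ground_truth.set_index(["subject_id", "date"])
    pr = pairs.set_index(["subject_id", "hba1c_date"])
    common = pr.index.intersection(gt.index)
    if len(common) == 0:
        raise ValueError("no overlap between pipeline pairs and ground truth")
    missing = pr.index.difference(gt.index)
    if len(missing) > 0:
        raise ValueError(f"{len(missing)} pipeline pairs have no ground-truth visit")
    err = (pr.loc[common, "discordance"]
           - gt.loc[common, "true_discordance"]).to_numpy(dtype=float)
    from .discordance import classify  # local import avoids cycle at module load
    true_groups = classify(gt.loc[common, "true_discordance"].to_numpy())
    agree = float((pr.loc[common, "group"].to_numpy() == true_groups).mean())
    b1 = float(fitted_model.coef_[0])
    se1 = float(fitted_model.se_[1])
    report = {
        "n_matched": int(len(common)),
        "discordance_rmse": float(np.sqrt(np.mean(err ** 2))),
        "discordance_max_abs_err": float(np.max(np.abs(err))),
        "discordance_within_tol": bool(np.sqrt(np.mean(err ** 2)) <= discordance_tol),
        "group_agreement": agree,
        "beta1": b1,
        "beta1_within_z": bool(abs(b1 - 1.0) <= beta1_z * se1),
        "beta2_positive": bool(fitted_model.coef_[1] > 0),
    }
    return report
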