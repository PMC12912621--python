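"""End-to-end orchestration with plain CSV/JSON artifacts per stage.

Stages: simulate (optional) -> pair -> analyze -> adjust -> report. Each
stage reads the previous stage's files and writes its own, so a chained
subcommand run and :func:`run_pipeline` produce identical artifacts; all
randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import model as mdl
from .discordance import (add_discordance, groupwise_kruskal_wallis,
                          interval_discordance_correlation, persistence_rate,
                          prevalence, reclassification_rate, sankey_table,
                          transition_table)
from .io import (DEFAULT_COVERAGE_THRESHOLD, clean_trace, read_cgm_csv,
                 read_hba1c_csv)
from .pairing import (DEFAULT_MIN_ACTIVE_DAYS, DEFAULT_MIN_PAIRS,
                      DEFAULT_WINDOW_DAYS, build_pairs, cohort_summary,
                      filter_eligible_subjects)
from .simulate import SyntheticConfig, simulate_cohort
from .stats import meng_test

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


class RunConfig(BaseModel):
    """Run configuration: either input CSV paths or a simulate block."""

    cgm_csv: str | None = None
    hba1c_csv: str | None = None
    glucose_unit: str = "mg/dL"
    sampling_interval: int = 5
    simulate: SyntheticConfig | None = None

    window_days: int = Field(DEFAULT_WINDOW_DAYS, gt=0)
    min_active_days: int = Field(DEFAULT_MIN_ACTIVE_DAYS, gt=0)
    coverage_threshold: float = Field(DEFAULT_COVERAGE_THRESHOLD, gt=0, le=1)
    discordance_threshold: float = Field(0.5, gt=0)
    min_pairs: int = Field(DEFAULT_MIN_PAIRS, ge=2)

    include_covariates: bool = False
    gam_lite: bool = False
    cv_folds: int = Field(5, ge=2)
    seed: int = 0

    output_dir: str = "agmi_run"

    @model_validator(mode="after")
    def _check(self):
        has_files = self.cgm_csv is not None and self.hba1c_csv is not None
        if not has_files and self.simulate is None:
            raise ValueError("provide cgm_csv+hba1c_csv or a simulate block")
        return self


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Generate a synthetic cohort and write its CSV/ground-truth artifacts."""
    if config.simulate is None:
        raise ValueError("no simulate block in configuration")
    outdir.mkdir(parents=True, exist_ok=True)
    traces, records, truth = simulate_cohort(config.simulate, config.window_days)
    frames = []
    for sid, tr in traces.items():
        f = tr.data.copy()
        f.insert(0, "subject_id", sid)
        frames.append(f)
    cgm = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject_id", "timestamp", "glucose"])
    cgm.to_csv(outdir / "cgm.csv", index=False)
    records.rename(columns={"hba1c": "hba1c_percent"}).to_csv(
        outdir / "hba1c.csv", index=False)
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    _write_json(outdir / "config.json",
                json.loads(config.model_dump_json(exclude={"output_dir"})))
    logger.info("simulate: %d subjects, %d visits", truth["subject_id"].nunique(),
                len(truth))


def stage_pair(config: RunConfig, outdir: Path) -> None:
    """Read, clean, window-join and filter; writes pairs.csv and qc.json."""
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        cgm_path, hba1c_path = outdir / "cgm.csv", outdir / "hba1c.csv"
        interval = config.simulate.sampling_interval
        unit = "mg/dL"
    else:
        cgm_path, hba1c_path = Path(config.cgm_csv), Path(config.hba1c_csv)
        interval = config.sampling_interval
        unit = config.glucose_unit
    for p in (cgm_path, hba1c_path):
        if not p.exists():
            raise FileNotFoundError(f"expected upstream artifact {p}; "
                                    "run the simulate stage or point to input CSVs")
    traces = read_cgm_csv(cgm_path, glucose_unit=unit, sampling_interval=interval)
    cleaned = {sid: clean_trace(t) for sid, t in traces.items()}
    records = read_hba1c_csv(hba1c_path)
    pairs = build_pairs(cleaned, records, config.window_days,
                        config.min_active_days, config.coverage_threshold)
    eligible = filter_eligible_subjects(pairs, config.min_pairs)
    eligible.to_csv(outdir / "pairs.csv", index=False)
    qc = {sid: t.qc.as_dict() for sid, t in sorted(cleaned.items())}
    _write_json(outdir / "qc.json", {
        "per_subject": qc,
        "n_hba1c_records": int(len(records)),
        "n_pairs_windowed": int(len(pairs)),
        "n_pairs_eligible": int(len(eligible)),
        "n_subjects_eligible": int(eligible["subject_id"].nunique()) if len(eligible) else 0,
    })
    logger.info("pair: %d records -> %d windowed -> %d eligible pairs",
                len(records), len(pairs), len(eligible))


def stage_analyze(config: RunConfig, outdir: Path) -> None:
    """Discordance, phenotypes, transitions and longitudinal statistics."""
    pairs_path = outdir / "pairs.csv"
    if not pairs_path.exists():
        raise FileNotFoundError(f"expected upstream artifact {pairs_path}; run 'pair' first")
    pairs = pd.read_csv(pairs_path, parse_dates=["hba1c_date", "window_start",
                                                 "window_end"])
    if pairs.empty:
        raise ValueError("analyze: the pair table is empty")
    ann = add_discordance(pairs, config.discordance_threshold)
    ann.to_csv(outdir / "pairs_annotated.csv", index=False)
    analysis: dict = {"cohort_summary": cohort_summary(ann)}
    analysis["prevalence"] = {
        "ge_0.5": prevalence(ann, 0.5),
        "ge_1.0": prevalence(ann, 1.0),
    }
    max_idx = int(ann["pair_index"].max())
    sankey = sankey_table(ann, min(2, max_idx)) if max_idx >= 1 else pd.DataFrame()
    sankey.to_csv(outdir / "transitions.csv", index=False)
    persistence = {}
    if max_idx >= 1:
        tab = transition_table(ann, 1)
        for g in ("positive", "negative"):
            try:
                persistence[g] = persistence_rate(tab, g)
            except ValueError as exc:
                persistence[g] = str(exc)
    analysis["persistence_at_pair_1"] = persistence
    try:
        analysis["reclassification_rate"] = reclassification_rate(ann)
    except ValueError as exc:
        analysis["reclassification_rate"] = str(exc)
    try:
        r, p = interval_discordance_correlation(ann)
        analysis["interval_correlation"] = {"r": r, "p": p}
    except ValueError as exc:
        analysis["interval_correlation"] = str(exc)
    kw = {}
    for idx in range(0, min(2, max_idx) + 1):
        try:
            res = groupwise_kruskal_wallis(ann, idx)
            kw[str(idx)] = {"H": res.H, "p": res.p,
                            "group_sizes": list(res.group_sizes),
                            "tie_correction": res.tie_correction}
        except ValueError as exc:
            kw[str(idx)] = str(exc)
    analysis["kruskal_wallis_by_pair"] = kw
    _write_json(outdir / "analysis.json", analysis)
    logger.info("analyze: %d pairs, prevalence(0.5)=%.3f", len(ann),
                analysis["prevalence"]["ge_0.5"])


def stage_adjust(config: RunConfig, outdir: Path, model_source: str = "fit") -> None:
    """Fit (or load) the adjustment model and evaluate it; writes model/eval JSON."""
    path = outdir / "pairs_annotated.csv"
    if not path.exists():
        raise FileNotFoundError(f"expected upstream artifact {path}; run 'analyze' first")
    ann = pd.read_csv(path, parse_dates=["hba1c_date", "window_start", "window_end"])
    rows = mdl.make_model_rows(ann)
    if model_source == "default":
        coefs = mdl.load_default_model()
        model = coefs
        model_json = coefs
    else:
        fitted = mdl.fit_ols(rows, config.include_covariates)
        model = fitted
        model_json = fitted.coefficients()
    y = rows["hba1c"].to_numpy()
    unadj = mdl.evaluate(rows["gmi"].to_numpy(), y)
    adj_pred = mdl.apply_agmi(rows["gmi"].to_numpy(),
                              rows["prior_discordance"].to_numpy(),
                              rows["last_hba1c"].to_numpy(), model)
    adj = mdl.evaluate(adj_pred, y)
    r12 = float(np.corrcoef(rows["gmi"].to_numpy(), adj_pred)[0, 1])
    meng = meng_test(adj.r, unadj.r, r12, adj.n)
    evaluation = {
        "unadjusted": unadj.as_dict(),
        "adjusted": adj.as_dict(),
        "meng_test": {"z": meng.z, "p": meng.p, "r1": meng.r1, "r2": meng.r2,
                      "r12": meng.r12, "n": meng.n},
        "subgroups": mdl.subgroup_evaluate(rows, model, config.discordance_threshold),
    }
    if model_source != "default":
        evaluation["adjusted_cv"] = mdl.cross_validate_estimator(
            rows, mdl.GmiAdjuster(), config.cv_folds, config.seed).as_dict()
    if config.gam_lite:
        evaluation["gam_lite_cv"] = mdl.fit_gam_lite(
            rows, config.cv_folds, config.seed).as_dict()
    _write_json(outdir / "model.json", model_json)
    _write_json(outdir / "evaluation.json", evaluation)
    logger.info("adjust: n=%d rows, r %.3f -> %.3f", adj.n, unadj.r, adj.r)


def stage_report(config: RunConfig, outdir: Path) -> dict:
    """Assemble report.json from the stage artifacts (no recomputation)."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "config": json.loads(config.model_dump_json(exclude={"output_dir"}))}
    for name in ("qc", "analysis", "model", "evaluation"):
        path = outdir / f"{name}.json"
        if not path.exists():
            raise FileNotFoundError(f"expected upstream artifact {path}")
        report[name] = json.loads(path.read_text())
    _write_json(outdir / "report.json", report)
    return report


def run_pipeline(config: RunConfig, model_source: str = "fit") -> dict:
    """Execute every stage in order under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        stage_simulate(config, outdir)
    stage_pair(config, outdir)
    stage_analyze(config, outdir)
    stage_adjust(config, outdir, model_source)
    return stage_report(config, outdir)
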