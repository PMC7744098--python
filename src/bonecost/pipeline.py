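"""End-to-end orchestration: generate or load data, run descriptives,
cessation fits with AIC stepwise and FDR q-values, loss profiles, and
fishing offsets; write a JSON report plus CSV tables and a stage log."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cessation as ces
from . import descriptives as desc
from . import offsets as off
from . import production as prod
from .synthetic import (AgeSchedule, CohortParams, ScheduleParams,
                        SurvivalSchedule, TASKS, generate_cohort,
                        generate_schedules, read_cohort, read_schedules,
                        task_column, write_cohort, write_schedules)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

COMPARISONS = {
    # better-off profile first
    "fracture": (prod.CovariateProfile(fracture=False),
                 prod.CovariateProfile(fracture=True)),
    "fracture_bmd": (prod.CovariateProfile(fracture=False, bmd_offset_sd=+1.0),
                     prod.CovariateProfile(fracture=True, bmd_offset_sd=-1.0)),
}


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for a full analysis run.

    Either CSV paths for an existing cohort/schedule pair, or synthetic
    parameters (the default) from which both are generated.
    """

    cohort_csv: str | None = None
    schedules_csv: str | None = None
    tasks: tuple = TASKS
    comparisons: tuple = ("fracture", "fracture_bmd")
    alpha: float = 0.05
    fdr_method: str = "storey"
    days_per_year: float = 365.0
    seed: int = 0
    out_dir: str = "bonecost_out"
    cohort_params: CohortParams | None = None
    schedule_params: ScheduleParams | None = None

    def validate(self) -> None:
        if not self.tasks:
            raise PipelineError("config", "no tasks to analyze")
        bad = set(self.tasks) - set(TASKS)
        if bad:
            raise PipelineError("config", f"unknown tasks: {sorted(bad)}")
        bad = set(self.comparisons) - set(COMPARISONS)
        if bad:
            raise PipelineError("config", f"unknown comparisons: {sorted(bad)}")
        if not 0 < self.alpha < 1:
            raise PipelineError("config", "alpha must lie in (0, 1)")
        if self.days_per_year <= 0:
            raise PipelineError("config", "days_per_year must be positive")
        for path in (self.cohort_csv, self.schedules_csv):
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("tasks", "comparisons"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cohort_params" in raw and raw["cohort_params"] is not None:
            raw["cohort_params"] = CohortParams(**raw["cohort_params"])
        if "schedule_params" in raw and raw["schedule_params"] is not None:
            raw["schedule_params"] = ScheduleParams(**raw["schedule_params"])
        return cls(**raw)


def _log(lines: list, stage: str, t0: float, seed: int, note: str = "") -> None:
    lines.append(f"stage={stage} wall_s={time.perf_counter() - t0:.3f} "
                 f"seed={seed} {note}".rstrip())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write results.json, loss_profile.csv, offsets.csv
    and pipeline.log into the output directory; returns the report dict.

    Deterministic given the seed: identical configs produce byte-identical
    report and table files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report: dict = {"seed": config.seed, "tasks": list(config.tasks),
                    "alpha": config.alpha, "fdr_method": config.fdr_method}

    # -- data -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
        else:
            cparams = config.cohort_params or CohortParams()
            cohort = generate_cohort(replace(cparams, seed=config.seed))
        if config.schedules_csv:
            schedule, survival = read_schedules(config.schedules_csv)
        else:
            schedule, survival = generate_schedules(config.schedule_params)
    except Exception as e:  # noqa: BLE001 - re-labelled with the stage
        raise PipelineError("data", str(e)) from e
    _log(log, "data", t0, config.seed, f"n={len(cohort)}")

    # -- descriptives -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        descr: dict = {"prevalence": {}, "participation": {}}
        for sex in ("male", "female"):
            sub = cohort[cohort["sex"] == sex]
            for label, col in (("any", "fracture"),
                               ("conservative", "fracture_conservative")):
                est = desc.wald_prevalence_ci(int(sub[col].sum()), len(sub),
                                              alpha=config.alpha)
                descr["prevalence"][f"{sex}_{label}"] = est.to_dict()
        for task in config.tasks:
            col = task_column(task)
            sub = cohort.dropna(subset=[col])
            ceased = sub[col].astype(bool)
            frac = sub["fracture"].astype(bool)
            table = [[int((frac & ceased).sum()), int((frac & ~ceased).sum())],
                     [int((~frac & ceased).sum()), int((~frac & ~ceased).sum())]]
            descr["participation"][task] = desc.crosstab_test(table).to_dict()
    except Exception as e:
        raise PipelineError("descriptives", str(e)) from e
    report["descriptives"] = descr
    _log(log, "descriptives", t0, config.seed)

    # -- cessation models -------------------------------------------------
    t0 = time.perf_counter()
    try:
        fits: dict = {}
        fracture_ps = []
        for task in config.tasks:
            comp = ces.stepwise_compare(cohort, task)
            fits[task] = comp.to_dict()
            m1 = comp.fits[0]
            fracture_ps.append(float(m1.p_values[m1.covariates.index("fracture")]))
        qs = ces.qvalues(fracture_ps, method=config.fdr_method)
        report["cessation"] = {"models": fits,
                               "fracture_fdr": qs.to_dict()}
        hunting_fit = None
        if "hunting" in config.tasks:
            hunting_fit = ces.fit_cessation(cohort, "hunting",
                                            covariates=("age", "fracture", "bmd_sd"))
    except Exception as e:
        raise PipelineError("cessation", str(e)) from e
    _log(log, "cessation", t0, config.seed)

    # -- loss profiles and offsets ---------------------------------------
    loss_rows, offset_rows = [], []
    if hunting_fit is not None and hunting_fit.converged:
        t0 = time.perf_counter()
        try:
            report["loss"] = {}
            report["offsets"] = {}
            for name in config.comparisons:
                pa, pb = COMPARISONS[name]
                lp = prod.loss_profile(schedule, survival, hunting_fit, pa, pb,
                                       days_per_year=config.days_per_year)
                report["loss"][name] = {
                    "peak_daily_loss": lp.peak_daily_loss,
                    "peak_daily_loss_age": lp.peak_daily_loss_age,
                    "peak_future_loss": lp.peak_future_loss,
                    "peak_future_loss_age": lp.peak_future_loss_age,
                }
                for a, dl, fl in zip(lp.ages, lp.daily_loss, lp.future_loss):
                    loss_rows.append({"comparison": name, "age": int(a),
                                      "daily_loss": round(dl, 6),
                                      "future_loss": round(fl, 3)})
                report["offsets"][name] = _offsets(lp, schedule, offset_rows, name)
        except Exception as e:
            raise PipelineError("loss", str(e)) from e
        _log(log, "loss", t0, config.seed)

    # -- outputs ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        (out / "results.json").write_text(
            json.dumps(_sanitize(report), indent=2, sort_keys=True,
                       allow_nan=False) + "\n")
        pd.DataFrame(loss_rows, columns=["comparison", "age", "daily_loss",
                                         "future_loss"]).to_csv(
            out / "loss_profile.csv", index=False)
        pd.DataFrame(offset_rows, columns=["comparison", "kind", "age",
                                           "value", "units"]).to_csv(
            out / "offsets.csv", index=False)
    except Exception as e:
        raise PipelineError("report", str(e)) from e
    _log(log, "report", t0, config.seed)
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return report


def _offsets(lp: prod.LossProfile, schedule: AgeSchedule,
             offset_rows: list, name: str) -> dict:
    peak_age = lp.peak_daily_loss_age
    daily = off.offset_minutes(lp.peak_daily_loss,
                               schedule.value_at(peak_age, "fishing_return"),
                               schedule.value_at(peak_age, "fishing_min_day"),
                               age=peak_age)
    i_max = int(np.argmax(schedule.fishing_return))
    i_min = int(np.argmin(schedule.fishing_return))
    start_age = float(lp.ages[0])
    future = float(lp.future_loss[0])
    cum_max = off.cumulative_offset(
        future, float(schedule.fishing_return[i_max]),
        float(schedule.fishing_min_day[i_max]), start_age=start_age,
        rate_basis="max_observed")
    cum_min = off.cumulative_offset(
        future, float(schedule.fishing_return[i_min]),
        float(schedule.fishing_min_day[i_min]), start_age=start_age,
        rate_basis="min_observed")
    offset_rows.append({"comparison": name, "kind": "daily_additional_min",
                        "age": int(peak_age),
                        "value": round(daily.additional_min_day, 3),
                        "units": "min/day"})
    for cum in (cum_max, cum_min):
        offset_rows.append({"comparison": name,
                            "kind": f"cumulative_hours_{cum.rate_basis}",
                            "age": int(start_age),
                            "value": round(cum.additional_hours, 3),
                            "units": "hr"})
    return {"daily_at_peak": daily.to_dict(),
            "cumulative_max_rate": cum_max.to_dict(),
            "cumulative_min_rate": cum_min.to_dict()}


def _sanitize(obj):
    """Make the report strictly JSON: numpy scalars to Python, non-finite
    floats to null."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
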