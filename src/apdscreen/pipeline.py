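"""End-to-end orchestration: cohort in, analysis bundle out.

Chains the full screening analysis — simulate or read a cohort, derive
weekly parameters, summarize groups, per-parameter ROC with Youden
cut-offs, the composite-rule grid, simple logistic fits per parameter, and
two BIC-stepwise runs (the four screening parameters, then the same four
plus the two SD-Res variability covariates) — and writes every result as
CSV/JSON with a provenance header. Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .models import complete_cases, logistic_simple, stepwise_bic, summarize_cohort
from .records import CASE, Cohort, read_sessions, write_sessions
from .roc import HIGHER_IS_CASE, LOWER_IS_CASE, compute_roc
from .rules import grid_frame, rule_grid
from .synthetic import CohortConfig, sample_cohort
from .weekly import derive_cohort, parameters_frame

logger = logging.getLogger(__name__)

#: orientation of each screening parameter: which tail indicates dysfunction
ROC_DIRECTIONS = {
    "total_alarms": HIGHER_IS_CASE,
    "mean_final_drain_time": HIGHER_IS_CASE,
    "mean_netUF_lastfill": LOWER_IS_CASE,
    "days_negative_lastfill": HIGHER_IS_CASE,
    "mean_netUF_cycler": LOWER_IS_CASE,
    "mean_gcUF": LOWER_IS_CASE,
}

#: parameters entering rule construction and the stepwise model; the two
#: cycler-UF-based parameters are reported (ROC) but excluded here, their
#: discrimination being too weak to qualify for the rule set
MODEL_PARAMETERS = [
    "total_alarms",
    "mean_final_drain_time",
    "mean_netUF_lastfill",
    "days_negative_lastfill",
]

SDRES_PARAMETERS = ["sdres_netUF_lastfill", "sdres_gcUF"]


@dataclasses.dataclass
class RunConfig:
    """One pipeline run: exactly one input mode, toggles, output directory."""

    out_dir: str
    seed: int = 0
    cohort_config: CohortConfig | None = None
    sessions_csv: str | None = None
    do_roc: bool = True
    do_rules: bool = True
    do_models: bool = True
    ci_level: float = 0.95

    def __post_init__(self):
        if (self.cohort_config is None) == (self.sessions_csv is None):
            raise ValueError("exactly one of cohort_config / sessions_csv must be set")


def roc_values(params_list, name):
    """Pairwise-complete case/control value vectors for one parameter."""
    cases = [p.get(name) for p in params_list if p.group == CASE and p.get(name) is not None]
    controls = [p.get(name) for p in params_list if p.group != CASE and p.get(name) is not None]
    return cases, controls


def analyse_cohort(cohort: Cohort, ci_level: float = 0.95) -> dict:
    """Run every analysis stage in memory; returns a result bundle dict."""
    params_list = derive_cohort(cohort)
    bundle: dict = {"parameters": params_list, "summary": summarize_cohort(params_list)}

    rocs = {}
    for name, direction in ROC_DIRECTIONS.items():
        cases, controls = roc_values(params_list, name)
        if not cases or not controls:
            logger.warning("roc: parameter %s has an empty group; skipped", name)
            continue
        rocs[name] = compute_roc(name, cases, controls, direction, level=ci_level)
    bundle["roc"] = rocs

    bundle["rule_grid"] = rule_grid(params_list)

    simple = {}
    for name in MODEL_PARAMETERS:
        x, y, dropped = complete_cases(params_list, [name])
        if dropped:
            logger.info("simple logistic %s: dropped %s (absent parameter)", name, dropped)
        try:
            simple[name] = logistic_simple(x[name], y, name=name, level=ci_level)
        except ValueError as err:
            logger.warning("simple logistic %s failed: %s", name, err)
    bundle["simple_fits"] = simple

    x, y, dropped = complete_cases(params_list, MODEL_PARAMETERS)
    bundle["stepwise"] = stepwise_bic(x, y, level=ci_level)
    bundle["stepwise_dropped"] = dropped

    x2, y2, dropped2 = complete_cases(params_list, MODEL_PARAMETERS + SDRES_PARAMETERS)
    bundle["stepwise_sdres"] = stepwise_bic(x2, y2, level=ci_level)
    bundle["stepwise_sdres_dropped"] = dropped2
    return bundle


def _roc_summary_dict(r):
    return {
        "parameter": r.parameter,
        "direction": r.direction,
        "auc": r.auc,
        "auc_ci": list(r.auc_ci),
        "auc_p": r.auc_p,
        "cutoff_rule": r.cutoff_rule,
        "cutoff": r.cutoff,
        "sensitivity": r.cutoff_sens,
        "sensitivity_ci": list(r.cutoff_sens_ci),
        "specificity": r.cutoff_spec,
        "specificity_ci": list(r.cutoff_spec_ci),
        "n_cases": r.n_cases,
        "n_controls": r.n_controls,
    }


def _fit_row(name, fit):
    if fit is None or not fit.ok:
        return {"parameter": name, "status": "not_converged_or_separated"}
    o, lo, hi = fit.or_per_unit[name]
    return {
        "parameter": name,
        "status": "ok",
        "beta": fit.beta[name],
        "or": o,
        "or_lo": lo,
        "or_hi": hi,
        "p": fit.p[name],
        "auc": fit.auc,
        "bic": fit.bic,
    }


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run and write the report bundle to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    if config.cohort_config is not None:
        cc = dataclasses.replace(config.cohort_config, seed=config.seed)
        cohort = sample_cohort(cc)
        source = f"simulated config={cc.hash()}"
    else:
        cohort = read_sessions(config.sessions_csv, strict=True)
        source = f"read {config.sessions_csv}"
    provenance = f"apdscreen v{__version__} seed={config.seed} source={source}"
    log(f"input: {source}; {len(cohort.cases)} cases, {len(cohort.controls)} controls")

    write_sessions(cohort, out / "sessions.csv", provenance_header=provenance)

    bundle = analyse_cohort(cohort, ci_level=config.ci_level)
    params_list = bundle["parameters"]
    _write_csv(parameters_frame(params_list), out / "weekly_parameters.csv", provenance)
    log(f"derived weekly parameters for {len(params_list)} patients")
    no_lastfill = [p.patient_id for p in params_list if p.n_lastfill_days == 0]
    if no_lastfill:
        log(f"patients without last fill (last-fill parameters absent): {no_lastfill}")

    _write_csv(bundle["summary"], out / "group_summary.csv", provenance)

    if config.do_roc:
        pts = []
        for name, r in bundle["roc"].items():
            for t, s, sp in r.points:
                pts.append({"parameter": name, "threshold": t, "sensitivity": s, "specificity": sp})
        _write_csv(pd.DataFrame(pts), out / "roc_points.csv", provenance)
        summaries = {name: _roc_summary_dict(r) for name, r in bundle["roc"].items()}
        (out / "roc_summary.json").write_text(
            json.dumps({"provenance": provenance, "roc": summaries}, indent=2, sort_keys=True) + "\n"
        )
        log(f"roc: {len(summaries)} parameter curves")

    if config.do_rules:
        grid = bundle["rule_grid"]
        _write_csv(grid_frame(grid), out / "rule_grid.csv", provenance)
        (out / "rule_grid.json").write_text(
            json.dumps({"provenance": provenance, "grid": grid}, indent=2, sort_keys=True) + "\n"
        )
        log("screening rule grid evaluated (2 combinations x k=1..3 + alarms-only)")

    if config.do_models:
        rows = [_fit_row(name, bundle["simple_fits"].get(name)) for name in MODEL_PARAMETERS]
        sw, sw2 = bundle["stepwise"], bundle["stepwise_sdres"]
        for row in rows:
            row["stepwise_status"] = sw.status.get(row["parameter"], "NC")
        _write_csv(pd.DataFrame(rows), out / "logistic_models.csv", provenance)
        (out / "stepwise.json").write_text(
            json.dumps(
                {
                    "provenance": provenance,
                    "four_parameters": {
                        "selected": list(sw.selected),
                        "bic": sw.bic,
                        "status": sw.status,
                        "trace": [list(t) for t in sw.trace],
                        "dropped_patients": bundle["stepwise_dropped"],
                    },
                    "with_sdres": {
                        "selected": list(sw2.selected),
                        "bic": sw2.bic,
                        "status": sw2.status,
                        "trace": [list(t) for t in sw2.trace],
                        "dropped_patients": bundle["stepwise_sdres_dropped"],
                    },
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        log(f"stepwise (4 params) selected: {list(sw.selected)}; "
            f"with SD-Res selected: {list(sw2.selected)}")

    (out / "run.log").write_text("# " + provenance + "\n" + "\n".join(log_lines) + "\n")
    return bundle
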