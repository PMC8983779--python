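"""Composite k-of-n screening rules for catheter dysfunction.

A :class:`Criterion` is a strict threshold comparison on one weekly
parameter ("> 7 alarms/week", "< 150 mL last-fill UF"); a
:class:`CompositeRule` flags a patient when at least k of its criteria
hold. The two reference combinations pair the alarm and drain-time
criteria with either the last-fill UF level (< 150 mL) or the count of
days with negative last-fill UF (> 2/week).

Boundary values do NOT fulfil a criterion (strict inequalities). A
parameter that is absent for a patient (no prescribed last fill) counts as
not fulfilled, so k-of-n rules stay evaluable for nightly-intermittent
patients.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import CASE, CONTROL
from .roc import clopper_pearson
from .weekly import PARAMETER_FIELDS, WeeklyParameters

GREATER_THAN = "greater_than"
LESS_THAN = "less_than"


@dataclass(frozen=True)
class Criterion:
    parameter: str
    direction: str
    threshold: float

    def __post_init__(self):
        if self.parameter not in PARAMETER_FIELDS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.direction not in (GREATER_THAN, LESS_THAN):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __str__(self) -> str:
        op = ">" if self.direction == GREATER_THAN else "<"
        return f"{self.parameter} {op} {self.threshold:g}"


@dataclass(frozen=True)
class CompositeRule:
    name: str
    criteria: tuple[Criterion, ...]
    k: int

    def __post_init__(self):
        if not (1 <= self.k <= len(self.criteria)):
            raise ValueError(f"k must lie in 1..{len(self.criteria)}, got {self.k}")


@dataclass(frozen=True)
class RuleEvaluation:
    rule: CompositeRule
    n_cases: int
    n_controls: int
    cases_flagged: int
    controls_flagged: int
    sensitivity: float
    false_positive_rate: float
    sensitivity_ci: tuple[float, float]
    false_positive_rate_ci: tuple[float, float]
    flags: dict  # patient_id -> bool

    @property
    def sensitivity_pct(self) -> float:
        return round(100.0 * self.sensitivity, 1)

    @property
    def false_positive_pct(self) -> float:
        return round(100.0 * self.false_positive_rate, 1)


def applies(criterion: Criterion, params: WeeklyParameters) -> bool | None:
    """Strict comparison; ``None`` (absent parameter) means not evaluable."""
    value = params.get(criterion.parameter)
    if value is None:
        return None
    if criterion.direction == GREATER_THAN:
        return bool(value > criterion.threshold)
    return bool(value < criterion.threshold)


def rule_flags(rule: CompositeRule, params: WeeklyParameters) -> bool:
    """True when at least k criteria hold; absent counts as not fulfilled."""
    hits = sum(1 for c in rule.criteria if applies(c, params) is True)
    return hits >= rule.k


def evaluate_rule(
    rule: CompositeRule, cohort_params: list[WeeklyParameters], level: float = 0.95
) -> RuleEvaluation:
    """Apply one rule to a cohort's derived parameters."""
    cases = [p for p in cohort_params if p.group == CASE]
    controls = [p for p in cohort_params if p.group == CONTROL]
    if not cases or not controls:
        raise ValueError("need at least one case and one control")
    flags = {p.patient_id: rule_flags(rule, p) for p in cohort_params}
    cases_flagged = sum(flags[p.patient_id] for p in cases)
    controls_flagged = sum(flags[p.patient_id] for p in controls)
    sens = cases_flagged / len(cases)
    fpr = controls_flagged / len(controls)
    return RuleEvaluation(
        rule=rule,
        n_cases=len(cases),
        n_controls=len(controls),
        cases_flagged=cases_flagged,
        controls_flagged=controls_flagged,
        sensitivity=sens,
        false_positive_rate=fpr,
        sensitivity_ci=clopper_pearson(cases_flagged, len(cases), level),
        false_positive_rate_ci=clopper_pearson(controls_flagged, len(controls), level),
        flags=flags,
    )


ALARMS_GT_7 = Criterion("total_alarms", GREATER_THAN, 7.0)
DRAIN_TIME_GT_22 = Criterion("mean_final_drain_time", GREATER_THAN, 22.0)
UF_LASTFILL_LT_150 = Criterion("mean_netUF_lastfill", LESS_THAN, 150.0)
NEG_DAYS_GT_2 = Criterion("days_negative_lastfill", GREATER_THAN, 2.0)

COMBINATION_1 = (ALARMS_GT_7, DRAIN_TIME_GT_22, UF_LASTFILL_LT_150)
COMBINATION_2 = (ALARMS_GT_7, DRAIN_TIME_GT_22, NEG_DAYS_GT_2)


def reference_rules() -> dict[str, CompositeRule]:
    """The frozen screening rule set at its published cut-offs.

    Both criterion triples instantiated at k = 1, 2, 3, plus the
    alarms-only single criterion.
    """
    rules = {"alarms_only": CompositeRule("alarms_only", (ALARMS_GT_7,), 1)}
    for label, crits in (("combination1", COMBINATION_1), ("combination2", COMBINATION_2)):
        for k in (1, 2, 3):
            name = f"{label}_k{k}"
            rules[name] = CompositeRule(name, crits, k)
    return rules


def rule_grid(cohort_params: list[WeeklyParameters]) -> dict:
    """Screening performance grid: 2 combinations × 4 columns × 2 rows.

    Columns: alarms-only, at least 1 of 3, at least 2 of 3, 3 of 3;
    rows: cases correctly identified (%) and false positive controls (%).
    """
    rules = reference_rules()
    grid: dict[str, dict[str, dict[str, float]]] = {}
    for label in ("combination1", "combination2"):
        cols = {}
        for col, rule_name in [
            ("alarms_only", "alarms_only"),
            ("at_least_1_of_3", f"{label}_k1"),
            ("at_least_2_of_3", f"{label}_k2"),
            ("3_of_3", f"{label}_k3"),
        ]:
            ev = evaluate_rule(rules[rule_name], cohort_params)
            cols[col] = {
                "cases_identified_pct": ev.sensitivity_pct,
                "false_positive_pct": ev.false_positive_pct,
            }
        grid[label] = cols
    return grid


def grid_frame(grid: dict):
    """The rule grid as a tidy DataFrame (rows: combination × measure)."""
    import pandas as pd

    rows = []
    for combo, cols in grid.items():
        for measure in ("cases_identified_pct", "false_positive_pct"):
            rows.append(
                {"combination": combo, "measure": measure}
                | {col: vals[measure] for col, vals in cols.items()}
            )
    return pd.DataFrame(rows)
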