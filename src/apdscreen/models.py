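"""Group comparisons and regression modelling.

Mann–Whitney U and Fisher's exact tests for group contrasts; simple
(one-covariate) logistic regression of case status on each weekly
parameter, reported as odds ratios per unit with Wald intervals;
bidirectional stepwise selection from the null model using the Bayesian
Information Criterion (BIC = −2·logL + k·ln(n)); odds multipliers for
clinically meaningful differences; and group summary tables.

At the study's size (14 cases / 19 controls) quasi-separation of strong
predictors is a live possibility; fits detect it and return an explicitly
flagged result rather than arbitrary coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import CASE
from .roc import auc_mann_whitney
from .weekly import WeeklyParameters

#: absolute log-odds beyond which a slope is treated as runaway (separation)
_SEPARATION_BETA = 30.0


def mwu_test(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U with two-sided p.

    Exact p for combined n ≤ 25 without ties; tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("need at least one value per group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Fisher's exact two-sided p for a 2×2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or (t != np.round(t)).any():
            raise ValueError("table must be 2×2 non-negative integer counts")
        t = t.astype(int)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def odds_multiplier(or_per_unit: float, delta_units: float) -> float:
    """Odds factor for a ``delta_units`` change given a per-unit odds ratio.

    ``delta_units`` may be negative: a 200 mL *decrease* with per-mL OR
    0.994 is ``odds_multiplier(0.994, -200) ≈ 3.33``.
    """
    if or_per_unit <= 0:
        raise ValueError("odds ratio must be positive")
    return float(or_per_unit ** delta_units)


@dataclass(frozen=True)
class LogisticFit:
    parameters: tuple[str, ...]
    beta: dict  # name -> coefficient (includes "const")
    or_per_unit: dict  # name -> (or, lo, hi)
    p: dict  # name -> Wald two-sided p
    bic: float
    auc: float
    n: int
    converged: bool
    separation: bool

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation


def _fit_logit(X: np.ndarray, y: np.ndarray, names: tuple[str, ...], level: float = 0.95) -> LogisticFit:
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            return LogisticFit(names, {}, {}, {}, math.inf, 0.5, len(y), False, True)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    separation = (
        not np.isfinite(params).all()
        or not np.isfinite(bse).all()
        or np.abs(params[1:]).max(initial=0.0) > _SEPARATION_BETA
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    all_names = ("const",) + names

    def _exp(v: float) -> float:
        return math.exp(min(v, 700.0))  # avoid overflow on runaway fits

    beta = dict(zip(all_names, params.tolist()))
    ors = {
        nm: (_exp(b), _exp(b - z * se), _exp(b + z * se))
        for nm, b, se in zip(all_names, params, bse)
        if nm != "const" and np.isfinite(b) and np.isfinite(se)
    }
    pvals = {
        nm: float(2 * stats.norm.sf(abs(b / se))) if se > 0 else float("nan")
        for nm, b, se in zip(all_names, params, bse)
        if nm != "const"
    }
    n, k = len(y), Xc.shape[1]
    bic = float(-2.0 * res.llf + k * math.log(n))
    with np.errstate(over="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = np.asarray(res.predict(Xc), dtype=float)
    auc = auc_mann_whitney(fitted[y == 1], fitted[y == 0]) if 0 < y.sum() < n else 0.5
    return LogisticFit(names, beta, ors, pvals, bic, auc, n, converged, separation)


def logistic_simple(x, y, name: str = "x", level: float = 0.95) -> LogisticFit:
    """Maximum-likelihood logistic fit of case status on one covariate.

    Returns odds ratio per unit with Wald CI; (quasi-)separation is
    detected and flagged on the result instead of reporting runaway
    numbers. Constant covariates carry no information and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(x) != len(y):
        raise ValueError("x and y must align")
    if y.min() == y.max():
        raise ValueError("need both labels present")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate carries no information")
    return _fit_logit(x[:, None], y, (name,), level=level)


def null_bic(y) -> float:
    """BIC of the intercept-only model."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    p = y.mean()
    llf = n * (p * math.log(p) + (1 - p) * math.log(1 - p)) if 0 < p < 1 else 0.0
    return float(-2.0 * llf + math.log(n))


@dataclass
class StepwiseResult:
    selected: tuple[str, ...]
    fit: LogisticFit | None  # None when the null model wins
    bic: float
    trace: list = field(default_factory=list)  # (action, name, bic) per step
    status: dict = field(default_factory=dict)  # candidate -> "selected" | "NC"
    n: int = 0


def stepwise_bic(candidates: dict, y, level: float = 0.95) -> StepwiseResult:
    """Bidirectional BIC-stepwise logistic selection from the null model.

    ``candidates`` maps covariate name to its per-patient values (complete
    cases only — assemble with :func:`complete_cases`). At each step the
    single add or drop that most reduces BIC is applied; the search stops
    when no move reduces BIC. Non-converged or separated candidate fits are
    skipped (logged in the trace). Unselected candidates get status "NC"
    (no candidate).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate covariates")
    y = np.asarray(y, dtype=int)
    arrays = {nm: np.asarray(v, dtype=float) for nm, v in candidates.items()}
    for nm, v in arrays.items():
        if len(v) != len(y):
            raise ValueError(f"candidate {nm!r} length mismatch")
        if not np.isfinite(v).all():
            raise ValueError(f"candidate {nm!r} has non-finite values; drop incomplete cases first")

    def fit_subset(names: tuple[str, ...]) -> LogisticFit | None:
        X = np.column_stack([arrays[nm] for nm in names])
        fit = _fit_logit(X, y, names, level=level)
        return fit if fit.ok else None

    current: tuple[str, ...] = ()
    current_bic = null_bic(y)
    current_fit: LogisticFit | None = None
    trace = [("start", "null", current_bic)]

    while True:
        moves = []  # (bic, action, name, fit)
        for nm in candidates:
            if nm not in current:
                fit = fit_subset(tuple(current) + (nm,))
                if fit is None:
                    trace.append(("skip_nonconverged", nm, math.nan))
                else:
                    moves.append((fit.bic, "add", nm, fit))
        for nm in current:
            rest = tuple(x for x in current if x != nm)
            if rest:
                fit = fit_subset(rest)
                if fit is not None:
                    moves.append((fit.bic, "drop", nm, fit))
            else:
                moves.append((null_bic(y), "drop", nm, None))
        if not moves:
            break
        best_bic, action, nm, fit = min(moves, key=lambda m: m[0])
        if best_bic >= current_bic - 1e-10:
            break
        if action == "add":
            current = tuple(current) + (nm,)
        else:
            current = tuple(x for x in current if x != nm)
        current_bic, current_fit = best_bic, fit
        trace.append((action, nm, best_bic))

    status = {nm: ("selected" if nm in current else "NC") for nm in candidates}
    return StepwiseResult(
        selected=current, fit=current_fit, bic=current_bic, trace=trace,
        status=status, n=len(y),
    )


def complete_cases(
    params_list: list[WeeklyParameters], names: list[str]
) -> tuple[dict, np.ndarray, list[str]]:
    """Assemble a complete-case design over the named weekly parameters.

    Patients with any absent parameter in the set are dropped pairwise and
    their ids returned, matching the study's handling of the
    nightly-intermittent control.
    """
    kept, dropped = [], []
    for p in params_list:
        if any(p.get(nm) is None for nm in names):
            dropped.append(p.patient_id)
        else:
            kept.append(p)
    x = {nm: np.array([p.get(nm) for p in kept], dtype=float) for nm in names}
    y = np.array([1 if p.group == CASE else 0 for p in kept], dtype=int)
    return x, y, dropped


def summarize_cohort(params_list: list[WeeklyParameters], parameters: list[str] | None = None) -> pd.DataFrame:
    """Per-group summary: n, mean, SD, median, IQR for each weekly parameter.

    Quartiles use linear interpolation (the numpy default convention);
    absent values are excluded pairwise.
    """
    from .weekly import PARAMETER_FIELDS

    parameters = parameters or PARAMETER_FIELDS
    rows = []
    for group in sorted({p.group for p in params_list}):
        members = [p for p in params_list if p.group == group]
        for nm in parameters:
            vals = np.array([p.get(nm) for p in members if p.get(nm) is not None], dtype=float)
            if vals.size == 0:
                continue
            q1, q3 = np.percentile(vals, [25, 75])
            rows.append(
                {
                    "group": group,
                    "parameter": nm,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "median": float(np.median(vals)),
                    "iqr": float(q3 - q1),
                }
            )
    return pd.DataFrame(rows)
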