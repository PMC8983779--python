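"""ROC construction, AUC estimation and comparison, and cut-off selection.

The AUC is computed as the Mann–Whitney statistic — the probability that a
random case scores above a random control, with half credit for ties. Its
confidence interval and test against AUC = 0.5 use the DeLong variance
(structural components); paired comparison of two AUCs on the same subjects
uses the paired DeLong covariance. Cut-offs are selected by maximizing
Youden's J = sensitivity + specificity − 1 over candidate thresholds placed
at midpoints between adjacent distinct observed values, and the selected
cut-off's sensitivity and specificity carry exact Clopper–Pearson binomial
intervals. Both interval flavours are reported side by side on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

HIGHER_IS_CASE = "higher_is_case"
LOWER_IS_CASE = "lower_is_case"


@dataclass(frozen=True)
class RocResult:
    parameter: str
    direction: str
    points: tuple[tuple[float, float, float], ...]  # (threshold, sens, spec)
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float | None
    cutoff: float
    cutoff_rule: str  # e.g. "> 7.0" or "< 150.0"
    cutoff_sens: float
    cutoff_spec: float
    cutoff_sens_ci: tuple[float, float]
    cutoff_spec_ci: tuple[float, float]
    n_cases: int
    n_controls: int


def _as_arrays(case_values, control_values):
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one value in each group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("scores must be finite")
    return x, y


def auc_mann_whitney(case_values, control_values) -> float:
    """AUC = [#(case > control) + ½·#(case = control)] / (m·n).

    Orientation must be pre-applied: higher score means case.
    """
    x, y = _as_arrays(case_values, control_values)
    psi = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
    return float(psi.mean())


def _delong_components(x: np.ndarray, y: np.ndarray):
    """DeLong structural components: per-case and per-control placements."""
    psi = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # one per case
    v01 = psi.mean(axis=0)  # one per control
    return auc, v10, v01


def delong_variance(case_values, control_values) -> float:
    x, y = _as_arrays(case_values, control_values)
    _, v10, v01 = _delong_components(x, y)
    s10 = float(np.var(v10, ddof=1)) if len(v10) > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if len(v01) > 1 else 0.0
    return s10 / len(x) + s01 / len(y)


def auc_ci_and_p(
    case_values, control_values, level: float = 0.95
) -> tuple[tuple[float, float], float | None]:
    """DeLong-variance normal CI (clipped to [0, 1]) and two-sided p vs 0.5.

    With degenerate variance (all placements tied) the p-value is returned
    as ``None``.
    """
    x, y = _as_arrays(case_values, control_values)
    auc = auc_mann_whitney(x, y)
    var = delong_variance(x, y)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(var)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    if se == 0.0:
        return ci, None
    p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    return ci, float(min(p, 1.0))


def delong_paired_test(values_a, values_b, labels) -> tuple[float, float | None, float | None]:
    """Paired DeLong test for ΔAUC of two scores on the same subjects.

    ``labels`` is truthy for cases. Returns ``(delta_auc, z, p)``; with a
    degenerate (zero) variance of the difference, z and p are ``None``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    lab = np.asarray([bool(v) for v in labels])
    if not (len(a) == len(b) == len(lab)):
        raise ValueError("values_a, values_b and labels must align")
    xa, ya = a[lab], a[~lab]
    xb, yb = b[lab], b[~lab]
    if xa.size == 0 or ya.size == 0:
        raise ValueError("need at least one case and one control")
    auc_a, v10a, v01a = _delong_components(xa, ya)
    auc_b, v10b, v01b = _delong_components(xb, yb)
    m, n = len(xa), len(ya)
    delta = auc_a - auc_b
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
    else:
        var = 0.0
    if var <= 0.0:
        return float(delta), None, None
    z = delta / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(min(p, 1.0))


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (beta-quantile) confidence interval for a proportion."""
    if trials < 1 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct values, plus ±inf endpoints."""
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_points(case_values, control_values):
    """Threshold sweep (oriented: higher ⇒ case) as (threshold, sens, spec)."""
    x, y = _as_arrays(case_values, control_values)
    thresholds = _candidate_thresholds(np.concatenate([x, y]))
    pts = []
    for t in thresholds:
        sens = float(np.mean(x > t))
        spec = float(np.mean(y <= t))
        pts.append((float(t), sens, spec))
    return pts


def select_cutoff(points) -> tuple[float, float, float]:
    """Pick the threshold maximizing Youden's J from oriented ROC points.

    Ties on J break toward higher specificity (fewer false positives), then
    toward the more extreme threshold in the case direction (larger, since
    points are oriented higher ⇒ case). Returns (threshold, sens, spec).
    """
    if not points:
        raise ValueError("empty ROC")
    finite = [p for p in points if math.isfinite(p[0])] or list(points)
    best = max(finite, key=lambda p: (p[1] + p[2] - 1.0, p[2], p[0]))
    return best


def compute_roc(
    parameter: str,
    case_values,
    control_values,
    direction: str = HIGHER_IS_CASE,
    level: float = 0.95,
) -> RocResult:
    """Full ROC analysis for one parameter: AUC, CI, p, and Youden cut-off.

    ``direction`` states which tail indicates a case; lower_is_case
    parameters (e.g. net UF) are analysed on the negated scale and the
    cut-off is reported back in original units as a "< t" rule.
    """
    if direction not in (HIGHER_IS_CASE, LOWER_IS_CASE):
        raise ValueError(f"unknown direction {direction!r}")
    x, y = _as_arrays(case_values, control_values)
    sign = 1.0 if direction == HIGHER_IS_CASE else -1.0
    xo, yo = sign * x, sign * y

    pts_oriented = roc_points(xo, yo)
    auc = auc_mann_whitney(xo, yo)
    ci, p = auc_ci_and_p(xo, yo, level=level)
    thr_o, sens, spec = select_cutoff(pts_oriented)

    cutoff = sign * thr_o
    rule = f"> {cutoff:g}" if direction == HIGHER_IS_CASE else f"< {cutoff:g}"
    m, n = len(x), len(y)
    sens_ci = clopper_pearson(round(sens * m), m, level)
    spec_ci = clopper_pearson(round(spec * n), n, level)

    points = tuple((sign * t, s, sp) for t, s, sp in pts_oriented)
    return RocResult(
        parameter=parameter,
        direction=direction,
        points=points,
        auc=auc,
        auc_ci=ci,
        auc_p=p,
        cutoff=float(cutoff),
        cutoff_rule=rule,
        cutoff_sens=sens,
        cutoff_spec=spec,
        cutoff_sens_ci=sens_ci,
        cutoff_spec_ci=spec_ci,
        n_cases=m,
        n_controls=n,
    )


def binormal_auc(mean_case: float, sd_case: float, mean_control: float, sd_control: float) -> float:
    """Closed-form AUC of two normal score distributions.

    Φ((μ_case − μ_control) / sqrt(σ_case² + σ_control²)); the population
    counterpart of the empirical Mann–Whitney AUC under normality.
    """
    denom = math.hypot(sd_case, sd_control)
    if denom == 0.0:
        return 0.5 if mean_case == mean_control else float(mean_case > mean_control)
    return float(stats.norm.cdf((mean_case - mean_control) / denom))
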