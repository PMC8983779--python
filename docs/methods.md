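# Methods

## Setting and data model

An APD cycler performs a night of automated fills and drains, then (for
most patients) instils an icodextrin "last fill" that dwells through the
day and is drained at the start of the next night's session. The machine
logs, per treatment: alarm events, the duration of the final drain phase,
fill and drain volumes for the nightly treatment and for the daytime
dwell, and the prescription from which the day's glucose load (grams of
glucose in fresh fluid; icodextrin is a glucose polymer and counts as
zero) follows.

The unit of analysis is a *patient week*: exactly 7 consecutive
patient-days plus a case/control label (case = radiologically confirmed
catheter dislocation). The last-fill drain volume is attributed to the
session that ends the dwell — the initial drain of that night's treatment
— which is how a cycler measures it; the attribution convention matters
only for SD-Res day indexing. Days are dense (1..7); a missing day is a
data error, not an imputation case, because the observation window is
defined as seven days of continuous treatment. One recognised prescription
variant is nightly intermittent PD without a last fill: such weeks carry
zero last-fill volumes and their last-fill parameters are *absent*, not
zero.

## Weekly screening parameters

Per patient: total alarms (sum), mean final drain time, mean last-fill net
UF (drain − fill over days with a prescribed last fill), count of
last-fill days with strictly negative net UF, mean cycler net UF
(last fill excluded), mean gcUF (daily cycler UF / daily glucose load),
and SD-Res for the daily last-fill UF and gcUF series.

Choices the source material leaves open, fixed here:

* Within-patient aggregation of drain time is the **mean** over the 7
  sessions (groups then summarize patient means), consistent with the
  other parameters and with a group mean and median that differ.
* "Negative UF" is **strict** (drain < fill); a zero-balance day does not
  count.
* gcUF uses the **cycler** net UF in the numerator and the glucose load of
  the nightly fresh fluid in the denominator; the icodextrin dwell
  contributes to neither.
* SD-Res is sqrt(SSE / (n − 2)) after OLS of the daily value on day index
  (the residual standard deviation with both regression degrees of freedom
  charged). It needs ≥ 3 finite values; below that the measure is absent.
  An exactly linear (or constant) series yields 0.
* Absent parameters propagate: analyses exclude such patients **pairwise**
  (only from analyses of the affected parameter), so a nightly-intermittent
  control still contributes alarms and drain-time information.

## ROC, cut-offs, intervals

The AUC is the Mann–Whitney statistic, P(case score > control score) with
half credit for ties, after orienting each parameter so that its
dysfunction tail scores high (alarms, drain time, negative-UF days: higher
is case; both UF parameters and gcUF: lower is case). Its variance comes
from the DeLong structural components (per-case and per-control placement
values); the CI is normal on that variance, clipped to [0, 1], and the
test against AUC = 0.5 uses the same variance. Paired AUC comparison uses
the paired DeLong covariance; a zero variance of the difference (e.g.
identical scores, or a perfect score against a constant, where every
placement component is tied) is reported as an explicit degenerate flag
rather than a p-value.

Candidate cut-offs are midpoints between adjacent distinct observed
values plus ±∞ endpoints — this is what turns count data into integer-ish
published rules like "> 7 alarms". The selected cut-off maximizes
Youden's J = sensitivity + specificity − 1; ties break toward higher
specificity (a screening rule should not over-flag), then toward the more
extreme threshold in the case direction. Rules are strict inequalities;
boundary values do not fire a criterion. Sensitivity and specificity at
the cut-off carry exact Clopper–Pearson (beta-quantile) intervals; the
AUC's interval is the DeLong one. Both interval flavours appear side by
side on every ROC result. No multiplicity correction is applied to the
per-parameter AUCs.

## Composite rules

A composite rule is a set of threshold criteria plus a minimum count k.
The reference set pairs "alarms > 7/week" and "drain time > 22 min" with
either "last-fill UF < 150 mL" (combination 1) or "negative-UF days > 2"
(combination 2), each at k = 1, 2, 3, plus the alarms-only rule. An
absent parameter counts as *not fulfilled* rather than excluding the
patient, so a k-of-3 rule stays evaluable for patients without a last
fill; the alternative (exclusion) would silently shrink the control group.
Sensitivity is over cases, the false-positive rate over controls, both
with Clopper–Pearson intervals, percentages reported to one decimal.
By construction raising k can only lower both rates, and loosening any
threshold can only raise them — both are tested as invariants.

## Group tests and logistic models

Mann–Whitney U is exact for combined n ≤ 25 without ties, tie-corrected
normal otherwise; Fisher's exact is the two-sided hypergeometric sum.
Simple logistic fits (one parameter at a time) are ML via IRLS
(statsmodels), reported as OR per unit with Wald intervals. At n = 33
with strong predictors quasi-separation is realistic; a fit whose slope
runs away (|β| > 30) or fails to converge is returned as a flagged
result, never as numbers.

Stepwise selection is bidirectional from the null model with
BIC = −2 logL + k ln(n) as the criterion: at each step the single add or
drop that most reduces BIC is applied; the search stops when no move
helps. n is the complete-case count for the candidate set, constant
across compared models; non-converged candidate fits are skipped and
logged in the trace. Unselected candidates are reported as "NC". A second
run adds the two SD-Res covariates to the four screening parameters to ask
whether within-week UF variability improves prediction. On ≤ 4 candidates
the greedy search is verified against exhaustive all-subsets BIC in the
tests. Group summaries use quartiles by linear interpolation (numpy's
default convention); printed IQRs cannot identify the original convention,
so one was fixed.

The pipeline computes and reports ROC results for all six parameters but
feeds only the four rule parameters (alarms, drain time, last-fill UF,
negative-UF days) into rule construction and the stepwise model; the two
cycler-UF-based parameters discriminate too weakly to qualify.

## Synthetic cohort generator

The generator's defaults *are* the study conditions: 14 cases, 19
controls, one week each. Weekly targets per patient are drawn from a
single-factor Gaussian copula anchored on the alarm latent with loading
ρ = 0.55 (|corr| on the latent scale between alarms and every other
parameter, signs chosen so clinically concordant directions — more
alarms, longer drains, less UF — correlate positively; other pairs get
the induced ρ² structure). Marginals:

| parameter | family | cases | controls |
|---|---|---|---|
| alarms/week | lognormal (median, mean) | (13.5, 19.3) | (5.0, 5.2) |
| final drain time, min | lognormal (median, mean) | (24.3, 29.0) | (17.7, 20.2) |
| last-fill net UF, mL | normal (mean, sd) | (−12.7, 153.3) | (206.3, 228.4) |
| cycler net UF, mL | normal (mean, sd) | (102.2, 372.2) | (393.5, 445.8) |

Lognormal marginals are moment-matched as μ = ln(median),
σ = sqrt(2 ln(mean/median)) — exact for both stated moments — and used
where the published medians sit far below the means (right skew); normal
marginals where they nearly coincide. Prescriptions are fixed at the
group medians: 9500 mL treatment volume, 1000 mL last fill, glucose load
124.1 g/day (cases) / 132.0 g/day (controls).

Each weekly target is decomposed into 7 sessions: the alarm total is
rounded and spread by a symmetric multinomial (conserved exactly; the
calibration is defined pre-rounding); daily drain time and drain volumes
are the weekly value plus Gaussian daily noise truncated at 0. Daily
noise SDs: 150 mL for last-fill UF — chosen so negative-UF days *emerge*
(cases ≈ 3–4/week, controls ≈ 1, matching the published counts) rather
than being sampled — and, as ordinary telemetry jitter, 5 min for drain
time and 150 mL for cycler volume. gcUF is never sampled; it is derived
downstream from cycler UF and glucose load, so the two cannot disagree.
A single seeded `numpy` generator is threaded through all sampling; a
config + seed determines the cohort byte-for-byte.

Under this calibration the population AUC for alarms on the latent scale,
Φ((ln 13.5 − ln 5.0)/sqrt(σ²_case + σ²_ctrl)), evaluates to ≈ 0.87 — the
same value as the study's empirical alarm AUC — and the binormal AUC of
last-fill UF from the table above is ≈ 0.79; these closed forms anchor
the acceptance checks.

What the generator does *not* emulate: within-week trends (day effects,
prescription changes), heavy-tailed alarm bursts, measurement rounding of
the cycler, and any between-parameter correlation structure beyond the
single factor. Passing tests therefore show that the analysis machinery
recovers the intended structure from data *like* the study's summaries,
not that the study's patient-level results are reproduced exactly —
patient data were never deposited, so study-size results are checked as
stochastic bands (e.g. the median 2-of-3 sensitivity across 500 replicate
cohorts within ±15 percentage points of 85.7%) rather than point targets.

## Problem sizes and numerical conventions

Calibration checks use 10,000–20,000 draws per group (Monte-Carlo SE
bands at 3–4 SE); replicate-band checks use 500 study-size cohorts;
coverage of the Clopper–Pearson interval is simulated at n = 14 with
10,000 replicates. Ties in the multinomial day allocation, threshold
midpoints, and BIC comparisons (strict improvement required, tolerance
1e−10) are the only tie-sensitive points, and each is pinned by a test.
Degenerate inputs — empty groups, constant covariates, all-tied scores,
< 3 SD-Res points, zero glucose load, no last fill — either raise a
specific error or return an explicit absent/flagged value; nothing is
silently imputed.

## Known limitations

* The copula scope (within-group, single factor) is a modelling choice;
  the published correlations were reported without group stratification.
* DeLong intervals at n = 14/19 are asymptotic; they clip at 1.0 for
  near-perfect parameters.
* The stepwise procedure considers main effects only.
* Published derived figures are reproduced from printed precision; e.g. a
  printed per-alarm OR of 1.298 compounds to 38.5 over 14 alarms, while a
  source computed from unrounded coefficients would give a slightly
  different factor.
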