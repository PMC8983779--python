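"""Evaluate the composite k-of-n screening rules on a synthetic cohort.

The reference rule set pairs 'alarms > 7/week' and 'drain time > 22 min'
with either 'last-fill UF < 150 mL' (combination 1) or 'negative-UF days
> 2/week' (combination 2). Raising k trades sensitivity for fewer false
positives; the 2-of-3 rule keeps most of the alarms-only sensitivity while
flagging fewer controls.
"""

import apdscreen as a
from apdscreen.rules import grid_frame

params = a.derive_cohort(a.sample_cohort(a.default_config(seed=1)))
grid = a.rule_grid(params)

print(grid_frame(grid).to_string(index=False))
print()
ev = a.evaluate_rule(a.reference_rules()["combination1_k2"], params)
print(f"combination 1, at least 2 of 3: sensitivity {ev.sensitivity_pct}% "
      f"({ev.cases_flagged}/{ev.n_cases} cases), false positives "
      f"{ev.false_positive_pct}% ({ev.controls_flagged}/{ev.n_controls} controls)")
lo, hi = ev.sensitivity_ci
print(f"sensitivity 95% Clopper-Pearson CI: [{lo:.2f}, {hi:.2f}]")
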