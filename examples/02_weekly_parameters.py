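"""Derive the weekly screening parameters for a single hand-built week.

One patient-week of telemetry collapses to the screening profile: total
alarms, mean final drain time, mean last-fill net UF, days with negative
last-fill UF, mean cycler net UF, gcUF, and the SD-Res variability of the
daily last-fill UF and gcUF series.
"""

import apdscreen as a

daily_uf = [-5.0, -3.0, 10.0, -1.0, 2.0, -4.0, 6.0]  # mL, drain minus fill
sessions = tuple(
    a.CyclerSession(
        patient_id="demo", day_index=d + 1, n_alarms=[2, 1, 0, 3, 1, 0, 2][d],
        final_drain_time_min=25.0 + d,
        cycler_fill_ml=9500.0, cycler_drain_ml=9620.0,
        lastfill_fill_ml=1000.0, lastfill_drain_ml=1000.0 + daily_uf[d],
        glucose_load_g=124.1,
    )
    for d in range(7)
)
week = a.PatientWeek("demo", a.CASE, sessions)
p = a.derive_weekly(week)

print(f"total alarms/week:        {p.total_alarms}")
print(f"mean final drain time:    {p.mean_final_drain_time:.1f} min")
print(f"mean net UF of last fill: {p.mean_netUF_lastfill:+.1f} mL")
print(f"days with negative UF:    {p.days_negative_lastfill} of {p.n_lastfill_days}")
print(f"mean cycler net UF:       {p.mean_netUF_cycler:+.1f} mL")
print(f"mean gcUF:                {p.mean_gcUF:.3f} mL/g")
print(f"SD-Res last-fill UF:      {p.sdres_netUF_lastfill:.2f} mL")
print("A week like this (alarms > 7 is false, but negative-UF days > 2 is")
print("true) fulfils part of the composite screening rule, not all of it.")
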