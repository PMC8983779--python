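"""Derive per-patient weekly screening parameters from a 7-day session log.

The screening parameters are: total alarms/week; mean final drain time;
mean net ultrafiltration (UF) of the last fill (daytime dwell); number of
days with negative last-fill UF; mean net UF of the cycler treatment
(last fill excluded); mean glucose-corrected UF (gcUF = cycler UF / glucose
load); and two within-patient variability measures, the standard deviation
of residuals (SD-Res) from an OLS fit of the daily last-fill UF and daily
gcUF series on day index.

Net UF is drain minus fill; negative UF means fluid was retained. Patients
without a prescribed last fill (nightly intermittent PD) have the last-fill
parameters flagged absent (``None``) rather than set to zero, and are
excluded pairwise from analyses of those parameters only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .records import CyclerSession, PatientWeek


class UndefinedValue(ValueError):
    """A parameter is undefined for this input (e.g. no last fill)."""


@dataclass(frozen=True)
class WeeklyParameters:
    patient_id: str
    group: str
    total_alarms: int
    mean_final_drain_time: float
    mean_netUF_lastfill: float | None
    days_negative_lastfill: int | None
    mean_netUF_cycler: float
    mean_gcUF: float | None
    sdres_netUF_lastfill: float | None
    sdres_gcUF: float | None
    n_lastfill_days: int

    def get(self, name: str):
        return getattr(self, name)


#: WeeklyParameters fields usable as screening parameters.
PARAMETER_FIELDS = [
    "total_alarms",
    "mean_final_drain_time",
    "mean_netUF_lastfill",
    "days_negative_lastfill",
    "mean_netUF_cycler",
    "mean_gcUF",
    "sdres_netUF_lastfill",
    "sdres_gcUF",
]


def net_uf_lastfill(session: CyclerSession) -> float:
    """Net UF of the daytime dwell: drain minus fill, in mL.

    Raises :class:`UndefinedValue` when no last fill was prescribed that day.
    """
    if session.lastfill_fill_ml == 0:
        raise UndefinedValue(
            f"{session.patient_id} day {session.day_index}: no last fill"
        )
    return session.lastfill_drain_ml - session.lastfill_fill_ml


def net_uf_cycler(session: CyclerSession) -> float:
    """Net UF of the nightly cycler treatment (last fill excluded), mL."""
    return session.cycler_drain_ml - session.cycler_fill_ml


def gc_uf(session: CyclerSession) -> float:
    """Glucose-corrected UF: cycler net UF (mL) per gram of glucose infused."""
    if session.glucose_load_g == 0:
        raise UndefinedValue(
            f"{session.patient_id} day {session.day_index}: zero glucose load"
        )
    return net_uf_cycler(session) / session.glucose_load_g


def glucose_load(bags: list[tuple[float, float]]) -> float:
    """Total grams of glucose in fresh PD fluid from ``(volume mL, g/L)`` bags.

    Icodextrin is a glucose polymer, not glucose: icodextrin bags carry
    concentration 0 and contribute nothing.
    """
    total = 0.0
    for volume_ml, conc_g_per_l in bags:
        if volume_ml < 0 or conc_g_per_l < 0:
            raise ValueError("bag volume and concentration must be >= 0")
        total += volume_ml / 1000.0 * conc_g_per_l
    return total


def sd_res(daily_values: list[tuple[int, float]], min_days: int = 3) -> float:
    """Standard deviation of residuals from OLS of value on day index.

    The per-patient expected daily value is the least-squares line over the
    week; variability is summarized as sqrt(SSE / (n - 2)). Requires at
    least ``min_days`` (and >= 3, for positive residual degrees of freedom)
    finite values; otherwise raises :class:`UndefinedValue`.
    """
    pts = [(d, v) for d, v in daily_values if math.isfinite(v)]
    if len(pts) < max(min_days, 3):
        raise UndefinedValue(
            f"need >= {max(min_days, 3)} finite values, got {len(pts)}"
        )
    x = np.array([d for d, _ in pts], dtype=float)
    y = np.array([v for _, v in pts], dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    if sse <= 1e-18 * max(1.0, float(y @ y)):  # numerically exact fit
        return 0.0
    return math.sqrt(sse / (len(pts) - 2))


def derive_weekly(week: PatientWeek) -> WeeklyParameters:
    """Derive all weekly screening parameters for one patient."""
    week.validate()
    sessions = week.sorted_sessions()

    total_alarms = int(sum(s.n_alarms for s in sessions))
    mean_drain_time = float(np.mean([s.final_drain_time_min for s in sessions]))
    mean_uf_cycler = float(np.mean([net_uf_cycler(s) for s in sessions]))

    lastfill_days = [s for s in sessions if s.lastfill_fill_ml > 0]
    n_lastfill_days = len(lastfill_days)
    if n_lastfill_days > 0:
        ufs = [net_uf_lastfill(s) for s in lastfill_days]
        mean_uf_lastfill = float(np.mean(ufs))
        days_negative = int(sum(1 for u in ufs if u < 0))
        try:
            sdres_lastfill = sd_res([(s.day_index, net_uf_lastfill(s)) for s in lastfill_days])
        except UndefinedValue:
            sdres_lastfill = None
    else:
        mean_uf_lastfill = None
        days_negative = None
        sdres_lastfill = None

    gcuf_days = [(s.day_index, gc_uf(s)) for s in sessions if s.glucose_load_g > 0]
    mean_gcuf = float(np.mean([v for _, v in gcuf_days])) if gcuf_days else None
    try:
        sdres_gcuf = sd_res(gcuf_days) if gcuf_days else None
    except UndefinedValue:
        sdres_gcuf = None

    return WeeklyParameters(
        patient_id=week.patient_id,
        group=week.group,
        total_alarms=total_alarms,
        mean_final_drain_time=mean_drain_time,
        mean_netUF_lastfill=mean_uf_lastfill,
        days_negative_lastfill=days_negative,
        mean_netUF_cycler=mean_uf_cycler,
        mean_gcUF=mean_gcuf,
        sdres_netUF_lastfill=sdres_lastfill,
        sdres_gcUF=sdres_gcuf,
        n_lastfill_days=n_lastfill_days,
    )


def derive_cohort(cohort) -> list[WeeklyParameters]:
    """Derive weekly parameters for every patient in a cohort."""
    return [derive_weekly(p) for p in cohort.patients]


def parameters_frame(params: list[WeeklyParameters]):
    """Weekly parameters as a pandas DataFrame, one row per patient."""
    import pandas as pd

    cols = [f.name for f in fields(WeeklyParameters)]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in params], columns=cols)


def read_parameters(path) -> list[WeeklyParameters]:
    """Read a weekly-parameters CSV (as written by the pipeline) back in.

    Empty cells become absent (``None``) fields.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#", dtype={"patient_id": str, "group": str})
    out = []
    for r in df.to_dict("records"):
        def opt(name, cast=float):
            v = r.get(name)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else cast(v)

        out.append(
            WeeklyParameters(
                patient_id=str(r["patient_id"]),
                group=str(r["group"]),
                total_alarms=int(r["total_alarms"]),
                mean_final_drain_time=float(r["mean_final_drain_time"]),
                mean_netUF_lastfill=opt("mean_netUF_lastfill"),
                days_negative_lastfill=opt("days_negative_lastfill", int),
                mean_netUF_cycler=float(r["mean_netUF_cycler"]),
                mean_gcUF=opt("mean_gcUF"),
                sdres_netUF_lastfill=opt("sdres_netUF_lastfill"),
                sdres_gcUF=opt("sdres_gcUF"),
                n_lastfill_days=int(r["n_lastfill_days"]),
            )
        )
    return out
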