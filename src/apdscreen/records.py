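"""Data model and CSV I/O for APD cycler session logs.

A *session* is one patient-day of cycler telemetry: alarm count, duration of
the final drain phase, fill/drain volumes for the nightly cycler treatment,
fill/drain volumes for the daytime dwell ("last fill", typically icodextrin),
and the day's glucose load. Seven consecutive sessions plus a case/control
label form a :class:`PatientWeek`; a list of weeks forms a :class:`Cohort`.

The interchange format is a long-format CSV, one row per patient-day, with
columns ``patient_id, group, day_index, n_alarms, final_drain_time_min,
cycler_fill_ml, cycler_drain_ml, lastfill_fill_ml, lastfill_drain_ml,
glucose_load_g``. The last-fill drain volume is attributed to the session
that ends the daytime dwell (the initial drain of that night's treatment).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

CSV_COLUMNS = [
    "patient_id",
    "group",
    "day_index",
    "n_alarms",
    "final_drain_time_min",
    "cycler_fill_ml",
    "cycler_drain_ml",
    "lastfill_fill_ml",
    "lastfill_drain_ml",
    "glucose_load_g",
]

_INT_FIELDS = {"day_index", "n_alarms"}


class InvariantError(ValueError):
    """A cohort, week, or session violates a structural invariant."""


@dataclass(frozen=True)
class CyclerSession:
    """One patient-day of cycler telemetry."""

    patient_id: str
    day_index: int
    n_alarms: int
    final_drain_time_min: float
    cycler_fill_ml: float
    cycler_drain_ml: float
    lastfill_fill_ml: float
    lastfill_drain_ml: float
    glucose_load_g: float

    def validate(self) -> None:
        if not (1 <= self.day_index <= 7):
            raise InvariantError(
                f"{self.patient_id}: day_index {self.day_index} outside 1..7"
            )
        if self.n_alarms < 0 or int(self.n_alarms) != self.n_alarms:
            raise InvariantError(
                f"{self.patient_id} day {self.day_index}: "
                f"n_alarms must be a non-negative integer, got {self.n_alarms}"
            )
        for name in (
            "final_drain_time_min",
            "cycler_fill_ml",
            "cycler_drain_ml",
            "lastfill_fill_ml",
            "lastfill_drain_ml",
            "glucose_load_g",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvariantError(
                    f"{self.patient_id} day {self.day_index}: "
                    f"{name} must be finite and >= 0, got {v}"
                )


@dataclass(frozen=True)
class PatientWeek:
    """Seven consecutive sessions for one patient, plus the group label.

    ``covariates`` is a pass-through map (age, D/P creatinine, ...) never
    consumed by any computation here.
    """

    patient_id: str
    group: str
    sessions: tuple[CyclerSession, ...]
    covariates: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in (CASE, CONTROL):
            raise InvariantError(
                f"{self.patient_id}: group must be '{CASE}' or '{CONTROL}', "
                f"got {self.group!r}"
            )
        if len(self.sessions) != 7:
            raise InvariantError(
                f"{self.patient_id}: expected exactly 7 sessions, "
                f"got {len(self.sessions)}"
            )
        days = sorted(s.day_index for s in self.sessions)
        if days != [1, 2, 3, 4, 5, 6, 7]:
            raise InvariantError(
                f"{self.patient_id}: day_index set must be exactly 1..7, got {days}"
            )
        for s in self.sessions:
            s.validate()
        # nightly-intermittent patients (no prescribed last fill all week)
        # must not report a last-fill drain on any day
        if all(s.lastfill_fill_ml == 0 for s in self.sessions):
            if any(s.lastfill_drain_ml != 0 for s in self.sessions):
                raise InvariantError(
                    f"{self.patient_id}: lastfill_drain_ml must be 0 on every "
                    "day when no last fill is prescribed all week"
                )

    @property
    def has_lastfill(self) -> bool:
        return any(s.lastfill_fill_ml > 0 for s in self.sessions)

    def sorted_sessions(self) -> tuple[CyclerSession, ...]:
        return tuple(sorted(self.sessions, key=lambda s: s.day_index))


@dataclass
class Cohort:
    """A labelled collection of patient weeks."""

    patients: list[PatientWeek]
    provenance: str = ""

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvariantError(f"duplicate patient_ids: {dupes}")
        for p in self.patients:
            p.validate()

    @property
    def cases(self) -> list[PatientWeek]:
        return [p for p in self.patients if p.group == CASE]

    @property
    def controls(self) -> list[PatientWeek]:
        return [p for p in self.patients if p.group == CONTROL]

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        """Restrict to the given patients (e.g. sensitivity re-analyses)."""
        keep = set(patient_ids)
        return Cohort(
            patients=[p for p in self.patients if p.patient_id in keep],
            provenance=self.provenance + " (subset)",
        )


def read_sessions(path, strict: bool = True) -> Cohort:
    """Read a long-format session CSV into a :class:`Cohort`.

    With ``strict`` on, any invariant violation raises
    :class:`InvariantError`. With ``strict`` off, offending patients are
    dropped and each drop is logged with its reason.
    """
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "group": str},
        comment="#",
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    numeric_cols = [c for c in CSV_COLUMNS if c not in ("patient_id", "group")]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((converted.isna()).idxmax()) + 2  # header + 1-based
            raise ValueError(f"non-numeric or missing value in '{col}' at CSV row {row}")
        df[col] = converted

    patients: list[PatientWeek] = []
    for pid, rows in df.groupby("patient_id", sort=False):
        groups = rows["group"].unique()
        try:
            if len(groups) != 1:
                raise InvariantError(f"{pid}: inconsistent group labels {list(groups)}")
            sessions = tuple(
                CyclerSession(
                    patient_id=str(pid),
                    day_index=int(r.day_index),
                    n_alarms=int(r.n_alarms),
                    final_drain_time_min=float(r.final_drain_time_min),
                    cycler_fill_ml=float(r.cycler_fill_ml),
                    cycler_drain_ml=float(r.cycler_drain_ml),
                    lastfill_fill_ml=float(r.lastfill_fill_ml),
                    lastfill_drain_ml=float(r.lastfill_drain_ml),
                    glucose_load_g=float(r.glucose_load_g),
                )
                for r in rows.itertuples()
            )
            week = PatientWeek(patient_id=str(pid), group=str(groups[0]), sessions=sessions)
            week.validate()
        except InvariantError as err:
            if strict:
                raise
            logger.warning("dropping patient %s: %s", pid, err)
            continue
        patients.append(week)

    cohort = Cohort(patients=patients, provenance=str(path))
    if strict:
        cohort.validate()
    return cohort


def write_sessions(cohort: Cohort, path, provenance_header: str | None = None) -> None:
    """Write a cohort as the long-format session CSV (round-trip exact).

    Volumes and times are serialized via ``repr`` of the float, so
    ``read_sessions(write_sessions(c)) == c`` field-for-field.
    """
    cohort.validate()
    records = []
    for p in cohort.patients:
        for s in p.sorted_sessions():
            records.append(
                {
                    "patient_id": p.patient_id,
                    "group": p.group,
                    "day_index": s.day_index,
                    "n_alarms": s.n_alarms,
                    "final_drain_time_min": s.final_drain_time_min,
                    "cycler_fill_ml": s.cycler_fill_ml,
                    "cycler_drain_ml": s.cycler_drain_ml,
                    "lastfill_fill_ml": s.lastfill_fill_ml,
                    "lastfill_drain_ml": s.lastfill_drain_ml,
                    "glucose_load_g": s.glucose_load_g,
                }
            )
    df = pd.DataFrame.from_records(records, columns=CSV_COLUMNS)
    # repr round-trips doubles exactly; pandas' default float formatting may not
    for col in df.columns:
        if col not in _INT_FIELDS and col not in ("patient_id", "group") and len(df):
            df[col] = df[col].map(lambda v: repr(float(v)))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance_header:
            fh.write(f"# {provenance_header}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
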