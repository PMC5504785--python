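"""Community- vs hospital-acquired typing of alerts via admission spells.

Each alert is related to the patient's inpatient spells and assigned one of
four mutually exclusive types, in precedence order:

1. ``CA_ON_ADMISSION`` — the alerting test was taken on an admission day.
   The injury originated beforehand, so these count as community-acquired
   even though the test happened in hospital.
2. ``HA`` — the test falls strictly inside a spell (after admission day,
   no later than discharge day).
3. ``CA_ADMITTED_7D`` — a community test followed by an admission within
   the next seven days (inclusive).
4. ``CA_NOT_ADMITTED`` — everything else.

Overlapping or same-day-abutting spells are merged first; an open discharge
extends to the study end.  ``first_alerts`` extracts each patient's
chronologically first alert as the cross-sectional view of where AKI
originates.
"""

from __future__ import annotations

from datetime import date, timedelta
from enum import Enum

import pandas as pd

__all__ = [
    "AlertType",
    "normalise_spells",
    "classify_alert_date",
    "classify_alerts",
    "first_alerts",
]

ADMISSION_WINDOW_DAYS = 7


class AlertType(Enum):
    CA_NOT_ADMITTED = "CA_NOT_ADMITTED"
    CA_ADMITTED_7D = "CA_ADMITTED_7D"
    CA_ON_ADMISSION = "CA_ON_ADMISSION"
    HA = "HA"

    @property
    def community(self) -> bool:
        return self is not AlertType.HA


def normalise_spells(
    spells: list[tuple[date, date | None]], study_end: date
) -> list[tuple[date, date]]:
    """Close open discharges at the study end and merge overlapping spells.

    Spells that overlap or share a day are merged into one contiguous
    interval; an admission after the previous discharge starts a new spell.
    """
    closed = []
    for admit, discharge in spells:
        d = study_end if discharge is None else discharge
        if admit > d:
            raise ValueError(f"spell admitted {admit} after discharge {d}")
        closed.append((admit, d))
    closed.sort()
    merged: list[tuple[date, date]] = []
    for admit, d in closed:
        if merged and admit <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], d))
        else:
            merged.append((admit, d))
    return merged


def classify_alert_date(
    test_date: date,
    spells: list[tuple[date, date]],
    window_days: int = ADMISSION_WINDOW_DAYS,
) -> tuple[AlertType, date | None]:
    """Type one alert against normalised spells; returns (type, linked admit).

    When several future admissions fall inside the seven-day window the
    earliest is linked.
    """
    for admit, _ in spells:
        if test_date == admit:
            return AlertType.CA_ON_ADMISSION, admit
    for admit, discharge in spells:
        if admit < test_date <= discharge:
            return AlertType.HA, admit
    horizon = test_date + timedelta(days=window_days)
    future = [a for a, _ in spells if test_date < a <= horizon]
    if future:
        return AlertType.CA_ADMITTED_7D, min(future)
    return AlertType.CA_NOT_ADMITTED, None


def classify_alerts(
    alerts: pd.DataFrame,
    admissions: pd.DataFrame,
    study_end: date,
    window_days: int = ADMISSION_WINDOW_DAYS,
) -> pd.DataFrame:
    """Add ``aki_type`` and ``linked_admit_date`` columns to an alerts table.

    ``admissions`` needs columns ``patient_id, admit_date, discharge_date``
    (empty discharge = still admitted / open).
    """
    adm = admissions.copy()
    adm["admit_date"] = pd.to_datetime(adm["admit_date"]).dt.date
    adm["discharge_date"] = pd.to_datetime(adm["discharge_date"]).dt.date
    by_patient: dict[str, list[tuple[date, date]]] = {}
    for pid, grp in adm.groupby("patient_id", sort=False):
        raw = [
            (a, None if pd.isna(d) else d)
            for a, d in zip(grp["admit_date"], grp["discharge_date"])
        ]
        by_patient[str(pid)] = normalise_spells(raw, study_end)

    out = alerts.copy()
    out["test_date"] = pd.to_datetime(out["test_date"]).dt.date
    types, linked = [], []
    for pid, td in zip(out["patient_id"], out["test_date"]):
        t, link = classify_alert_date(td, by_patient.get(str(pid), []), window_days)
        types.append(t.value)
        linked.append(link)
    out["aki_type"] = types
    out["linked_admit_date"] = linked
    return out


def first_alerts(classified: pd.DataFrame) -> pd.DataFrame:
    """Each patient's chronologically first alert (same-day ties by seq)."""
    if classified.empty:
        return classified.copy()
    return (
        classified.sort_values(["patient_id", "test_date", "seq"], kind="mergesort")
        .groupby("patient_id", as_index=False, sort=True)
        .head(1)
        .reset_index(drop=True)
    )
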