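"""Practice and patient cohort selection.

Linked-lab coverage is only complete for practices that routinely use the
contributing hospital laboratories.  Selection therefore proceeds in two
steps: (1) biochemical testing rates for a designated *anchor* set of
practices (the city practices known to use the labs) define a reference
distribution, whose Tukey lower fence — Q1 − 1.5 × IQR — becomes the
inclusion threshold for every practice, anchors included; (2) patients are
kept when they are adults at the start of the observation year and were
continuously registered with a surviving practice for the whole study
period (look-back plus observation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "CohortDefinition",
    "compute_testing_rates",
    "tukey_lower_fence",
    "select_practices",
    "select_patients",
    "select_cohort",
    "DAYS_PER_YEAR",
]

logger = logging.getLogger("akilinked")

DAYS_PER_YEAR = 365  # rate denominator; scale-equivalent for the fence


@dataclass(frozen=True)
class CohortDefinition:
    """Outcome of the two-step selection, with per-reason exclusion counts."""

    fence: float
    rates: pd.DataFrame                  # practice_id, tests, rate, anchor
    included_practices: frozenset[str]
    included_patients: frozenset[str]
    exclusions: pd.DataFrame             # patient_id, reason

    @property
    def exclusion_counts(self) -> dict[str, int]:
        return self.exclusions["reason"].value_counts().to_dict()


def compute_testing_rates(
    scr: pd.DataFrame,
    patients: pd.DataFrame,
    practices: pd.DataFrame,
    period: tuple[date, date],
) -> pd.DataFrame:
    """Tests per registered patient per year, for every practice.

    The numerator counts SCr results whose patient is registered with the
    practice; the denominator is list size times the period length in
    365-day years.  Practices with a zero list size are dropped with a
    warning (their rate is undefined).
    """
    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient registration rows: {sorted(set(dupes))}")
    unknown = set(patients["practice_id"]) - set(practices["practice_id"])
    if unknown:
        raise ValueError(f"patients reference unknown practice_id(s): {sorted(unknown)}")

    start, end = period
    years = ((end - start).days + 1) / DAYS_PER_YEAR
    if years <= 0:
        raise ValueError("period must span at least one day")

    counts = (
        scr.merge(patients[["patient_id", "practice_id"]], on="patient_id", how="inner")
        .groupby("practice_id", sort=True)
        .size()
    )
    out = practices[["practice_id"]].copy()
    if "anchor" in practices.columns:
        out["anchor"] = practices["anchor"].astype(bool).to_numpy()
    out["tests"] = out["practice_id"].map(counts).fillna(0).astype(int)
    list_size = practices["list_size"].to_numpy()
    zero = list_size <= 0
    if zero.any():
        logger.warning(
            "dropping %d practice(s) with zero list size from rate table", zero.sum()
        )
    out = out.loc[~zero].copy()
    out["rate"] = out["tests"] / (list_size[~zero] * years)
    return out.reset_index(drop=True)


def tukey_lower_fence(rates: "np.typing.ArrayLike") -> float:
    """Q1 − 1.5 × IQR with linearly interpolated quartiles.

    Needs at least four observations for the quartiles to be meaningful.
    """
    arr = np.asarray(rates, dtype=float)
    if arr.size < 4:
        raise ValueError(f"fence undefined for fewer than 4 rates (got {arr.size})")
    q1, q3 = np.percentile(arr, [25, 75])
    return float(q1 - 1.5 * (q3 - q1))


def select_practices(rates: pd.DataFrame, fence: float) -> frozenset[str]:
    """Keep practices whose rate is at or above the fence — anchors too.

    Only a strict shortfall excludes; a rate exactly on the fence stays in.
    """
    keep = frozenset(rates.loc[rates["rate"] >= fence, "practice_id"])
    if not keep:
        logger.warning("no practice survives the fence %.4g: empty cohort", fence)
    return keep


def select_patients(
    patients: pd.DataFrame,
    included_practices: frozenset[str] | set[str],
    study_period: tuple[date, date],
    obs_start: date | None = None,
    min_age: int = 18,
) -> tuple[frozenset[str], pd.DataFrame]:
    """Adults registered with an included practice for the whole study period.

    Age is whole years at ``obs_start`` (default: the study start) computed
    from birth year.  Each excluded patient is recorded under exactly one
    reason, checked in the order age, registration, practice.
    """
    study_start, study_end = study_period
    if obs_start is None:
        obs_start = study_start

    df = patients.copy()
    df["reg_start"] = pd.to_datetime(df["reg_start"]).dt.date
    df["reg_end"] = pd.to_datetime(df["reg_end"]).dt.date
    age = obs_start.year - df["birth_year"].astype(int)
    ok_age = age >= min_age
    ok_reg = (df["reg_start"] <= study_start) & (df["reg_end"] >= study_end)
    ok_prac = df["practice_id"].isin(included_practices)

    reason = np.select(
        [~ok_age, ~ok_reg, ~ok_prac], ["age", "registration", "practice"], default=""
    )
    exclusions = pd.DataFrame(
        {"patient_id": df["patient_id"], "reason": reason}
    ).query("reason != ''").reset_index(drop=True)
    included = frozenset(df.loc[ok_age & ok_reg & ok_prac, "patient_id"])
    return included, exclusions


def select_cohort(
    scr: pd.DataFrame,
    patients: pd.DataFrame,
    practices: pd.DataFrame,
    study_period: tuple[date, date],
    obs_start: date | None = None,
    min_age: int = 18,
) -> CohortDefinition:
    """Run both selection steps and return the full cohort definition."""
    rates = compute_testing_rates(scr, patients, practices, study_period)
    if "anchor" not in rates.columns:
        raise ValueError("practices table needs an 'anchor' column for the fence")
    anchor_rates = rates.loc[rates["anchor"], "rate"]
    fence = tukey_lower_fence(anchor_rates)
    included_practices = select_practices(rates, fence)
    included_patients, exclusions = select_patients(
        patients, included_practices, study_period, obs_start, min_age
    )
    return CohortDefinition(
        fence=fence,
        rates=rates,
        included_practices=included_practices,
        included_patients=included_patients,
        exclusions=exclusions,
    )
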