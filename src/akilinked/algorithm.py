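"""Staged AKI alerting from longitudinal serum creatinine.

The NHS England early-warning algorithm evaluates every serum creatinine
(SCr) result against two rolling baselines drawn from the patient's own
history:

* the lowest SCr in the 0–7 days preceding the result (short window), and
* the median SCr in the 8–365 days preceding it (long window).

A reference value ratio (RVR) is the index value divided by a baseline; the
*higher* RVR over the two windows is compared against staged thresholds
(1.5, 2, 3).  A low-RVR stage-1 alert is also raised when SCr rose by more
than 26 μmol/L over the preceding 48 h, implemented here at whole-day
resolution as a two-day window, and a very high absolute concentration
(≥ 354 μmol/L) escalates a ratio-qualifying result to stage 3.

All arithmetic is in μmol/L on calendar dates; an integer ``seq`` orders
multiple results within one patient-day.  Results outside the configured
observation interval contribute baselines but never alert themselves.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AlgorithmConfig",
    "ScrResult",
    "ReferenceValues",
    "Stage",
    "AkiAlert",
    "DataQualityError",
    "order_series",
    "short_window_min",
    "long_window_median",
    "rise_within_window",
    "reference_values",
    "stage_result",
    "evaluate_patient",
    "detect_alerts",
    "filter_plausible",
    "alerts_to_frame",
    "ALERTS_COLUMNS",
]

logger = logging.getLogger("akilinked")


class DataQualityError(ValueError):
    """Raised when input records violate the dataset key or value contracts."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlgorithmConfig:
    """Every numeric constant of the alerting algorithm.

    Defaults reproduce the national specification: baseline windows of
    0–7 and 8–365 days, ratio thresholds 1.5 / 2 / 3, an absolute stage-3
    concentration of 354 μmol/L, and a rise of more than 26 μmol/L within
    a two-day window (the whole-day proxy for 48 h).  The plausibility
    band quarantines physiologically impossible values before evaluation.
    """

    short_window_days: int = 7
    long_window_lo_days: int = 8
    long_window_hi_days: int = 365
    rise_threshold: float = 26.0      # μmol/L, strict (">26")
    rise_window_days: int = 2         # whole-day proxy for 48 h
    rvr_alert: float = 1.5
    rvr_stage2: float = 2.0
    rvr_stage3: float = 3.0
    abs_stage3_scr: float = 354.0     # μmol/L
    plausibility_lo: float = 5.0      # μmol/L, exclusive bounds
    plausibility_hi: float = 3000.0

    def __post_init__(self) -> None:
        if not (0 < self.rvr_alert < self.rvr_stage2 < self.rvr_stage3):
            raise ValueError(
                "ratio thresholds must satisfy 0 < rvr_alert < rvr_stage2 < rvr_stage3"
            )
        if not (self.short_window_days < self.long_window_lo_days
                <= self.long_window_hi_days):
            raise ValueError(
                "windows must satisfy short_window_days < long_window_lo_days"
                " <= long_window_hi_days"
            )
        if self.rise_threshold <= 0:
            raise ValueError("rise_threshold must be positive")
        if self.rise_window_days < 1:
            raise ValueError("rise_window_days must be at least 1 day")
        if not (0 < self.plausibility_lo < self.plausibility_hi):
            raise ValueError("plausibility band must satisfy 0 < lo < hi")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AlgorithmConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown AlgorithmConfig fields: {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str | Path) -> "AlgorithmConfig":
        """Read a YAML or JSON file whose keys mirror the field names."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        return cls.from_mapping(data or {})

    def replace(self, **changes: object) -> "AlgorithmConfig":
        return replace(self, **changes)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ScrResult:
    """One dated serum-creatinine measurement — the unit of evaluation.

    ``seq`` orders results taken on the same day (timestamps are not
    relied upon); ``(patient_id, test_date, seq)`` is unique in a dataset.
    """

    patient_id: str = field(compare=False)
    test_date: date = field(compare=True)
    seq: int = field(compare=True, default=0)
    value: float = field(compare=False, default=0.0)

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(
                f"SCr value must be positive, got {self.value} for "
                f"patient {self.patient_id} on {self.test_date}"
            )
        if self.seq < 0:
            raise ValueError("seq must be a non-negative integer")


@dataclass(frozen=True)
class ReferenceValues:
    """The two dynamically selected baselines and their ratios.

    ``rvr_higher`` is the maximum over whichever ratios exist; it is
    absent only when neither window holds a prior result.
    """

    rv_short: Optional[float] = None
    rv_long: Optional[float] = None
    rvr_short: Optional[float] = None
    rvr_long: Optional[float] = None
    rvr_higher: Optional[float] = None


class Stage(Enum):
    """Alert stage.  Severity is ordered AKI1 (either flavour) < AKI2 < AKI3."""

    AKI1_LOW_RVR = "AKI1_LOW_RVR"
    AKI1_HIGH_RVR = "AKI1_HIGH_RVR"
    AKI2 = "AKI2"
    AKI3 = "AKI3"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


_SEVERITY = {
    Stage.AKI1_LOW_RVR: 1,
    Stage.AKI1_HIGH_RVR: 1,
    Stage.AKI2: 2,
    Stage.AKI3: 3,
}


@dataclass(frozen=True)
class AkiAlert:
    """An index result that met the alerting criteria, with provenance."""

    patient_id: str
    test_date: date
    seq: int
    value: float
    stage: Stage
    references: ReferenceValues
    rise_48h: Optional[float] = None


# ---------------------------------------------------------------------------
# Series plumbing
# ---------------------------------------------------------------------------

def order_series(results: Iterable[ScrResult]) -> list[ScrResult]:
    """Sort one patient's results ascending by (test_date, seq).

    Rejects any duplicate (test_date, seq) pair — reproducible evaluation
    requires an unambiguous within-day order — naming the offending
    records in the error.
    """
    series = sorted(results, key=lambda r: (r.test_date, r.seq))
    if not series:
        return series
    pids = {r.patient_id for r in series}
    if len(pids) > 1:
        raise ValueError(f"series mixes patients: {sorted(pids)}")
    for a, b in zip(series, series[1:]):
        if (a.test_date, a.seq) == (b.test_date, b.seq):
            raise DataQualityError(
                f"duplicate (test_date, seq) for patient {a.patient_id}: "
                f"{a.test_date} seq {a.seq} with values {a.value} and {b.value}"
            )
    return series


# ---------------------------------------------------------------------------
# Baseline windows
# ---------------------------------------------------------------------------
#
# Window arithmetic is inclusive of both endpoints in whole days.  "0 days"
# means earlier results on the index date itself: same-day earlier-seq
# results are eligible for the short and rise windows, never the long one.

def short_window_min(
    series: Sequence[ScrResult], index: int, cfg: AlgorithmConfig
) -> Optional[float]:
    """Lowest SCr among priors 0–``short_window_days`` days before the index."""
    idx = series[index]
    lo = idx.test_date - timedelta(days=cfg.short_window_days)
    vals = [r.value for r in series[:index] if lo <= r.test_date <= idx.test_date]
    return min(vals) if vals else None


def long_window_median(
    series: Sequence[ScrResult], index: int, cfg: AlgorithmConfig
) -> Optional[float]:
    """Median SCr among priors 8–365 days before the index.

    An even count takes the mean of the two central values.
    """
    idx = series[index]
    lo = idx.test_date - timedelta(days=cfg.long_window_hi_days)
    hi = idx.test_date - timedelta(days=cfg.long_window_lo_days)
    vals = [r.value for r in series[:index] if lo <= r.test_date <= hi]
    return float(statistics.median(vals)) if vals else None


def rise_within_window(
    series: Sequence[ScrResult], index: int, cfg: AlgorithmConfig
) -> Optional[float]:
    """Index value minus the lowest prior within the rise window (two days)."""
    idx = series[index]
    lo = idx.test_date - timedelta(days=cfg.rise_window_days)
    vals = [r.value for r in series[:index] if lo <= r.test_date <= idx.test_date]
    return idx.value - min(vals) if vals else None


def reference_values(
    series: Sequence[ScrResult], index: int, cfg: AlgorithmConfig
) -> ReferenceValues:
    """Assemble both baselines and their ratios for one index result."""
    idx = series[index]
    rv_short = short_window_min(series, index, cfg)
    rv_long = long_window_median(series, index, cfg)
    rvr_short = idx.value / rv_short if rv_short is not None else None
    rvr_long = idx.value / rv_long if rv_long is not None else None
    present = [r for r in (rvr_short, rvr_long) if r is not None]
    return ReferenceValues(
        rv_short=rv_short,
        rv_long=rv_long,
        rvr_short=rvr_short,
        rvr_long=rvr_long,
        rvr_higher=max(present) if present else None,
    )


# ---------------------------------------------------------------------------
# Staging
# ---------------------------------------------------------------------------

def stage_result(
    value: float,
    refs: ReferenceValues,
    rise: Optional[float],
    cfg: AlgorithmConfig,
) -> Optional[Stage]:
    """Map one evaluated result to an alert stage, or None for no alert.

    Ratio thresholds are inclusive on their lower bound and exclusive on
    the upper ("RVR ≥ 1.5 and < 2"); the 48-h rise criterion is strict
    (a rise of *more than* 26 μmol/L).  The absolute criterion promotes a
    ratio-qualifying result (RVR ≥ 1.5) with SCr ≥ 354 μmol/L to stage 3.
    """
    if value <= 0:
        raise ValueError(f"SCr value must be positive, got {value}")
    r = refs.rvr_higher
    if r is not None:
        if r >= cfg.rvr_stage3 or (r >= cfg.rvr_alert and value >= cfg.abs_stage3_scr):
            return Stage.AKI3
        if r >= cfg.rvr_stage2:
            return Stage.AKI2
        if r >= cfg.rvr_alert:
            return Stage.AKI1_HIGH_RVR
    if rise is not None and rise > cfg.rise_threshold:
        return Stage.AKI1_LOW_RVR
    return None


# ---------------------------------------------------------------------------
# Per-patient evaluation
# ---------------------------------------------------------------------------

def evaluate_patient(
    series: Sequence[ScrResult],
    observation: tuple[date, date],
    cfg: AlgorithmConfig = AlgorithmConfig(),
) -> list[AkiAlert]:
    """Evaluate every in-observation result of one patient's ordered series.

    Results outside the (closed) observation interval contribute baselines
    only; the algorithm deliberately re-alerts on every qualifying result,
    so one AKI episode can yield a run of alerts.  Pure function of
    (series, observation, cfg).
    """
    obs_start, obs_end = observation
    if obs_start > obs_end:
        raise ValueError("observation interval start must not exceed end")
    alerts: list[AkiAlert] = []
    for i, res in enumerate(series):
        if not (obs_start <= res.test_date <= obs_end):
            continue
        refs = reference_values(series, i, cfg)
        rise = rise_within_window(series, i, cfg)
        stage = stage_result(res.value, refs, rise, cfg)
        if stage is not None:
            alerts.append(
                AkiAlert(
                    patient_id=res.patient_id,
                    test_date=res.test_date,
                    seq=res.seq,
                    value=res.value,
                    stage=stage,
                    references=refs,
                    rise_48h=rise,
                )
            )
    return alerts


# ---------------------------------------------------------------------------
# DataFrame front end
# ---------------------------------------------------------------------------

ALERTS_COLUMNS = [
    "patient_id",
    "test_date",
    "seq",
    "value_umol_l",
    "stage",
    "rv_short",
    "rv_long",
    "rvr_higher",
    "rise_window",
]


def filter_plausible(
    scr: pd.DataFrame, cfg: AlgorithmConfig = AlgorithmConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an SCr table into (plausible, quarantined) on the value band.

    Values outside the open interval (plausibility_lo, plausibility_hi)
    are excluded from evaluation and logged, implementing the data-quality
    screen for transcription artefacts (zero, negative or unit-confused
    values).
    """
    vals = pd.to_numeric(scr["value_umol_l"], errors="coerce")
    bad = ~(vals > cfg.plausibility_lo) | ~(vals < cfg.plausibility_hi)
    quarantined = scr.loc[bad].copy()
    if len(quarantined):
        logger.warning(
            "excluded %d SCr result(s) outside plausibility band (%g, %g) μmol/L",
            len(quarantined), cfg.plausibility_lo, cfg.plausibility_hi,
        )
    return scr.loc[~bad].copy(), quarantined


def detect_alerts(
    scr: pd.DataFrame,
    obs_start: date,
    obs_end: date,
    cfg: AlgorithmConfig = AlgorithmConfig(),
) -> pd.DataFrame:
    """Run the alerting algorithm over a whole SCr table.

    ``scr`` needs columns ``patient_id, test_date, value_umol_l`` and
    optionally ``seq`` (default 0).  Returns the alerts table in the
    standard output schema, one row per alert, in (patient, date, seq)
    order.  Plausibility filtering is the caller's job (see
    :func:`filter_plausible`); this function assumes clean input.
    """
    df = scr.copy()
    if "seq" not in df.columns:
        df["seq"] = 0
    df["seq"] = df["seq"].fillna(0).astype(int)
    df["test_date"] = pd.to_datetime(df["test_date"]).dt.date
    df["value_umol_l"] = pd.to_numeric(df["value_umol_l"])

    alerts: list[AkiAlert] = []
    for pid, grp in df.sort_values(["patient_id", "test_date", "seq"]).groupby(
        "patient_id", sort=True
    ):
        series = order_series(
            ScrResult(str(pid), row.test_date, int(row.seq), float(row.value_umol_l))
            for row in grp.itertuples(index=False)
        )
        alerts.extend(evaluate_patient(series, (obs_start, obs_end), cfg))
    return alerts_to_frame(alerts)


def alerts_to_frame(alerts: Sequence[AkiAlert]) -> pd.DataFrame:
    """Flatten alerts into the standard CSV schema (absent fields -> NaN)."""
    rows = [
        {
            "patient_id": a.patient_id,
            "test_date": a.test_date,
            "seq": a.seq,
            "value_umol_l": a.value,
            "stage": a.stage.value,
            "rv_short": a.references.rv_short,
            "rv_long": a.references.rv_long,
            "rvr_higher": a.references.rvr_higher,
            "rise_window": a.rise_48h,
        }
        for a in alerts
    ]
    return pd.DataFrame(rows, columns=ALERTS_COLUMNS)
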