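"""CSV schemas, validation/quarantine, the two report shapes, pipeline.

The pipeline runs cohort selection, alert detection and CA/HA typing over
a validated bundle of four linked CSVs, and produces:

* a demographic report — cohort, gender and age-band rows with the share
  of patients holding 0–1 vs 2+ SCr results, alerted-patient counts and
  alert counts (row-relative percentages);
* an alert-type report — first-alert and all-alert counts by the four
  CA/HA types with column-relative percentages and a CA subtotal;
* a data-quality log counting every quarantined row by reason, and a
  machine-readable run manifest (config hash, input checksums, stage
  counts).

Percentages are stored at full precision and rounded to one decimal only
at render time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .algorithm import AlgorithmConfig, detect_alerts
from .classification import AlertType, classify_alerts, first_alerts
from .cohort import CohortDefinition, select_cohort
from .synthetic import AGE_BAND_LABELS, age_band

__all__ = [
    "ValidatedBundle",
    "PipelineResult",
    "validate_bundle",
    "demographic_report",
    "alert_type_report",
    "render_report",
    "run_pipeline",
]

logger = logging.getLogger("akilinked")

SCHEMAS = {
    "patients": ["patient_id", "gender", "birth_year", "practice_id",
                 "reg_start", "reg_end"],
    "practices": ["practice_id", "list_size", "anchor"],
    "scr_results": ["patient_id", "test_date", "seq", "value_umol_l"],
    "admissions": ["patient_id", "admit_date", "discharge_date"],
}

_QUARANTINE_COLUMNS = ["table", "csv_line", "patient_id", "reason"]


@dataclass
class ValidatedBundle:
    patients: pd.DataFrame
    practices: pd.DataFrame
    scr: pd.DataFrame
    admissions: pd.DataFrame
    quarantine: pd.DataFrame

    @property
    def quality_log(self) -> pd.DataFrame:
        if self.quarantine.empty:
            return pd.DataFrame(columns=["table", "reason", "count"])
        return (
            self.quarantine.groupby(["table", "reason"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )


_OPTIONAL_COLUMNS = {"scr_results": {"seq"}}


def _check_header(df: pd.DataFrame, table: str) -> None:
    optional = _OPTIONAL_COLUMNS.get(table, set())
    missing = [c for c in SCHEMAS[table]
               if c not in df.columns and c not in optional]
    if missing:
        raise ValueError(f"{table}: malformed header, missing column(s) {missing}")


def _parse_dates(df: pd.DataFrame, table: str, columns: list[str],
                 allow_empty: tuple[str, ...] = ()) -> None:
    for col in columns:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna()
        if col in allow_empty:
            blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
            bad = bad & ~blank
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(
                f"{table}: unparseable date in column '{col}' at line {line}"
            )
        df[col] = parsed.dt.date


def validate_bundle(
    patients_path: str | Path,
    practices_path: str | Path,
    scr_path: str | Path,
    admissions_path: str | Path,
    cfg: AlgorithmConfig = AlgorithmConfig(),
) -> ValidatedBundle:
    """Load the four CSVs, enforcing schemas and quarantining bad rows.

    Malformed headers and unparseable dates are hard errors (the file is
    unusable); out-of-band values, orphan references and duplicate keys
    are quarantined row-wise with a reason, so one bad record never sinks
    a run.
    """
    frames = {}
    for name, path in [("patients", patients_path), ("practices", practices_path),
                       ("scr_results", scr_path), ("admissions", admissions_path)]:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        _check_header(df, name)
        frames[name] = df

    quarantine: list[tuple[str, int, str, str]] = []

    def _quarantine(table: str, rows: pd.DataFrame, reason: str) -> None:
        for idx, pid in zip(rows.index, rows.get("patient_id", rows.index)):
            quarantine.append((table, int(idx) + 2, str(pid), reason))

    # practices: numeric list size, boolean anchor
    prac = frames["practices"]
    prac["list_size"] = pd.to_numeric(prac["list_size"], errors="coerce")
    bad = prac["list_size"].isna() | (prac["list_size"] < 0)
    if bad.any():
        for idx in prac.index[bad]:
            quarantine.append(("practices", int(idx) + 2,
                               str(prac.loc[idx, "practice_id"]), "bad_list_size"))
    prac = prac.loc[~bad].copy()
    prac["list_size"] = prac["list_size"].astype(int)
    prac["anchor"] = (
        prac["anchor"].astype(str).str.strip().str.lower()
        .map({"1": True, "0": False, "true": True, "false": False})
        .fillna(False)
        .astype(bool)
    )

    # patients: parse dates, drop duplicates and orphan practices
    pat = frames["patients"]
    _parse_dates(pat, "patients", ["reg_start", "reg_end"])
    pat["birth_year"] = pd.to_numeric(pat["birth_year"], errors="coerce")
    bad = pat["birth_year"].isna()
    _quarantine("patients", pat.loc[bad], "bad_birth_year")
    pat = pat.loc[~bad].copy()
    pat["birth_year"] = pat["birth_year"].astype(int)
    dup = pat["patient_id"].duplicated(keep="first")
    _quarantine("patients", pat.loc[dup], "duplicate")
    pat = pat.loc[~dup].copy()
    orphan = ~pat["practice_id"].isin(set(prac["practice_id"]))
    _quarantine("patients", pat.loc[orphan], "orphan_practice")
    pat = pat.loc[~orphan].copy()
    known_patients = set(pat["patient_id"])

    # SCr results: numeric plausibility band, orphans, duplicate keys
    scr = frames["scr_results"]
    _parse_dates(scr, "scr_results", ["test_date"])
    if "seq" not in scr.columns:
        scr["seq"] = 0
    scr["seq"] = pd.to_numeric(scr["seq"], errors="coerce").fillna(0).astype(int)
    scr["value_umol_l"] = pd.to_numeric(scr["value_umol_l"], errors="coerce")
    bad = scr["value_umol_l"].isna()
    _quarantine("scr_results", scr.loc[bad], "non_numeric")
    scr = scr.loc[~bad].copy()
    bad = scr["value_umol_l"] <= 0
    _quarantine("scr_results", scr.loc[bad], "non-positive")
    scr = scr.loc[~bad].copy()
    bad = ~((scr["value_umol_l"] > cfg.plausibility_lo)
            & (scr["value_umol_l"] < cfg.plausibility_hi))
    _quarantine("scr_results", scr.loc[bad], "implausible")
    scr = scr.loc[~bad].copy()
    bad = ~scr["patient_id"].isin(known_patients)
    _quarantine("scr_results", scr.loc[bad], "orphan")
    scr = scr.loc[~bad].copy()
    key = ["patient_id", "test_date", "seq"]
    dup_any = scr.duplicated(key, keep=False)
    if dup_any.any():
        conflict = (
            scr.loc[dup_any].groupby(key)["value_umol_l"].nunique() > 1
        )
        conflict_keys = set(conflict.index[conflict])
        is_conflict = dup_any & scr.set_index(key).index.isin(conflict_keys)
        _quarantine("scr_results", scr.loc[is_conflict], "conflicting_duplicate")
        scr = scr.loc[~is_conflict].copy()
        dup = scr.duplicated(key, keep="first")
        _quarantine("scr_results", scr.loc[dup], "duplicate")
        scr = scr.loc[~dup].copy()

    # admissions: date order and orphans
    adm = frames["admissions"]
    _parse_dates(adm, "admissions", ["admit_date", "discharge_date"],
                 allow_empty=("discharge_date",))
    bad = ~adm["patient_id"].isin(known_patients)
    _quarantine("admissions", adm.loc[bad], "orphan")
    adm = adm.loc[~bad].copy()
    closed = adm["discharge_date"].notna()
    bad = closed & (adm["admit_date"] > adm["discharge_date"])
    _quarantine("admissions", adm.loc[bad], "negative_spell")
    adm = adm.loc[~bad].copy()

    q = pd.DataFrame(quarantine, columns=_QUARANTINE_COLUMNS)
    if len(q):
        logger.warning("quarantined %d row(s); see quality log", len(q))
    return ValidatedBundle(
        patients=pat.reset_index(drop=True),
        practices=prac.reset_index(drop=True),
        scr=scr.reset_index(drop=True),
        admissions=adm.reset_index(drop=True),
        quarantine=q,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _demo_row(group: str, label: str, pats: pd.DataFrame,
              counts: pd.Series, alerts: pd.DataFrame) -> dict:
    n = len(pats)
    ids = set(pats["patient_id"])
    c = counts.reindex(pats["patient_id"]).fillna(0)
    n2 = int((c >= 2).sum())
    if alerts.empty:
        alerted, n_alerts = 0, 0
    else:
        mask = alerts["patient_id"].isin(ids)
        alerted = int(alerts.loc[mask, "patient_id"].nunique())
        n_alerts = int(mask.sum())
    return {
        "group": group,
        "label": label,
        "n": n,
        "pct_scr_0_1": 100.0 * (n - n2) / n if n else 0.0,
        "pct_scr_2plus": 100.0 * n2 / n if n else 0.0,
        "patients_alerted": alerted,
        "pct_alerted": 100.0 * alerted / n if n else 0.0,
        "alerts": n_alerts,
    }


def demographic_report(
    cohort_patients: pd.DataFrame,
    scr: pd.DataFrame,
    alerts: pd.DataFrame,
    obs_start: date,
) -> pd.DataFrame:
    """Cohort / gender / age-band breakdown of SCr availability and alerts.

    ``scr`` should already be restricted to the window over which result
    availability is being described; percentages are row-relative and kept
    at full precision (rounding happens in :func:`render_report`).
    """
    pats = cohort_patients.copy()
    pats["age"] = obs_start.year - pats["birth_year"].astype(int)
    pats["band"] = pats["age"].map(age_band)
    counts = scr.groupby("patient_id").size() if len(scr) else pd.Series(dtype=int)

    rows = [_demo_row("cohort", "All", pats, counts, alerts)]
    for g in sorted(pats["gender"].astype(str).unique()):
        rows.append(_demo_row("gender", g, pats[pats["gender"] == g], counts, alerts))
    for band in AGE_BAND_LABELS:
        rows.append(_demo_row("age", band, pats[pats["band"] == band], counts, alerts))
    return pd.DataFrame(rows)


_TYPE_LABELS = {
    AlertType.CA_NOT_ADMITTED: "Not admitted CA-AKI",
    AlertType.CA_ADMITTED_7D: "CA-AKI admitted within 7 days",
    AlertType.CA_ON_ADMISSION: "CA-AKI identified on admission",
    AlertType.HA: "All HA-AKI",
}


def alert_type_report(classified: pd.DataFrame, first: pd.DataFrame) -> pd.DataFrame:
    """First-alert vs all-alert counts by CA/HA type with a CA subtotal.

    Percentages are column-relative; the three CA rows sum to the
    "All CA-AKI" row, and CA + HA = Total in both columns.
    """
    def counts(df: pd.DataFrame) -> dict[str, int]:
        if df.empty:
            return {t.value: 0 for t in AlertType}
        vc = df["aki_type"].value_counts()
        return {t.value: int(vc.get(t.value, 0)) for t in AlertType}

    fc, ac = counts(first), counts(classified)
    f_tot, a_tot = sum(fc.values()), sum(ac.values())
    ca = [AlertType.CA_NOT_ADMITTED, AlertType.CA_ADMITTED_7D,
          AlertType.CA_ON_ADMISSION]

    rows = []
    for t in ca:
        rows.append((_TYPE_LABELS[t], t.value, fc[t.value], ac[t.value]))
    rows.append(("All CA-AKI", "ALL_CA",
                 sum(fc[t.value] for t in ca), sum(ac[t.value] for t in ca)))
    rows.append((_TYPE_LABELS[AlertType.HA], AlertType.HA.value,
                 fc[AlertType.HA.value], ac[AlertType.HA.value]))
    rows.append(("Total", "TOTAL", f_tot, a_tot))

    out = pd.DataFrame(rows, columns=["label", "aki_type", "first_n", "all_n"])
    out["first_pct"] = np.where(f_tot, 100.0 * out["first_n"] / max(f_tot, 1), 0.0)
    out["all_pct"] = np.where(a_tot, 100.0 * out["all_n"] / max(a_tot, 1), 0.0)
    return out[["label", "aki_type", "first_n", "first_pct", "all_n", "all_pct"]]


def render_report(report: pd.DataFrame) -> str:
    """Plain-text table with percentages rounded to one decimal place."""
    shown = report.copy()
    for col in shown.columns:
        if str(col).startswith("pct") or str(col).endswith("pct"):
            shown[col] = shown[col].round(1)
    return shown.to_string(index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    bundle: ValidatedBundle
    cohort: CohortDefinition
    alerts: pd.DataFrame
    classified: pd.DataFrame
    first: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    manifest: dict


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    patients_path: str | Path,
    practices_path: str | Path,
    scr_path: str | Path,
    admissions_path: str | Path,
    study_start: date,
    obs_start: date,
    obs_end: date,
    cfg: AlgorithmConfig = AlgorithmConfig(),
    min_age: int = 18,
    scr_count_window: str = "study",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Cohort selection, detection, classification and both reports.

    ``scr_count_window`` controls whether the demographic report's 0–1 /
    2+ availability columns count results over the whole study period
    (look-back included, the default — look-back results contribute to
    detectability) or the observation year only.
    """
    if scr_count_window not in ("study", "observation"):
        raise ValueError("scr_count_window must be 'study' or 'observation'")
    bundle = validate_bundle(
        patients_path, practices_path, scr_path, admissions_path, cfg
    )
    cohort = select_cohort(
        bundle.scr, bundle.patients, bundle.practices,
        (study_start, obs_end), obs_start=obs_start, min_age=min_age,
    )
    if not cohort.included_patients:
        logger.warning("empty cohort: no patient passed selection")

    scr_cohort = bundle.scr[
        bundle.scr["patient_id"].isin(cohort.included_patients)
    ].reset_index(drop=True)
    alerts = detect_alerts(scr_cohort, obs_start, obs_end, cfg)
    adm_cohort = bundle.admissions[
        bundle.admissions["patient_id"].isin(cohort.included_patients)
    ].reset_index(drop=True)
    classified = classify_alerts(alerts, adm_cohort, study_end=obs_end)
    first = first_alerts(classified)

    cohort_patients = bundle.patients[
        bundle.patients["patient_id"].isin(cohort.included_patients)
    ].reset_index(drop=True)
    if scr_count_window == "observation":
        scr_for_counts = scr_cohort[
            (scr_cohort["test_date"] >= obs_start)
            & (scr_cohort["test_date"] <= obs_end)
        ]
    else:
        scr_for_counts = scr_cohort
    table2 = demographic_report(cohort_patients, scr_for_counts, alerts, obs_start)
    table3 = alert_type_report(classified, first)

    manifest = {
        "config": {
            **{k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
            "study_start": study_start.isoformat(),
            "obs_start": obs_start.isoformat(),
            "obs_end": obs_end.isoformat(),
            "min_age": min_age,
            "scr_count_window": scr_count_window,
        },
        "inputs": {
            "patients": _sha256(patients_path),
            "practices": _sha256(practices_path),
            "scr_results": _sha256(scr_path),
            "admissions": _sha256(admissions_path),
        },
        "counts": {
            "patients_read": int(len(bundle.patients)),
            "practices_read": int(len(bundle.practices)),
            "scr_read": int(len(bundle.scr)),
            "rows_quarantined": int(len(bundle.quarantine)),
            "fence": float(cohort.fence),
            "practices_included": len(cohort.included_practices),
            "patients_included": len(cohort.included_patients),
            "exclusions": {k: int(v) for k, v in cohort.exclusion_counts.items()},
            "scr_evaluated": int(len(scr_cohort)),
            "alerts": int(len(alerts)),
            "alerted_patients": int(alerts["patient_id"].nunique())
            if len(alerts) else 0,
            "first_alerts": int(len(first)),
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    result = PipelineResult(
        bundle, cohort, alerts, classified, first, table2, table3, manifest
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"patient_id": sorted(result.cohort.included_patients)}).to_csv(
        out / "cohort.csv", index=False
    )
    rates = result.cohort.rates
    (out / "cohort_report.json").write_text(
        json.dumps(
            {
                "fence": result.cohort.fence,
                "rates": {
                    str(r.practice_id): float(r.rate)
                    for r in rates.itertuples(index=False)
                },
                "included_practices": sorted(result.cohort.included_practices),
                "exclusion_counts": {
                    k: int(v) for k, v in result.cohort.exclusion_counts.items()
                },
            },
            indent=2,
        )
    )
    result.alerts.to_csv(out / "alerts.csv", index=False)
    result.classified.to_csv(out / "classified_alerts.csv", index=False)
    result.first.to_csv(out / "first_alerts.csv", index=False)
    result.table2.to_csv(out / "table2.csv", index=False)
    result.table3.to_csv(out / "table3.csv", index=False)
    result.bundle.quality_log.to_csv(out / "quality_log.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
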