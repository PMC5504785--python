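"""Validation, report shapes and end-to-end pipeline consistency."""

from datetime import date
from pathlib import Path

import pandas as pd
import pytest

from akilinked import (
    SimulationConfig,
    alert_type_report,
    demographic_report,
    generate,
    render_report,
    run_pipeline,
    validate_bundle,
)

STUDY_START = date(2013, 1, 1)
OBS_START = date(2014, 1, 1)
OBS_END = date(2014, 12, 31)


def write_bundle(tmp_path: Path, patients, practices, scr, admissions) -> dict:
    paths = {}
    for name, df in [("patients", patients), ("practices", practices),
                     ("scr_results", scr), ("admissions", admissions)]:
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def tiny_bundle(tmp_path: Path, scr_rows=None, adm_rows=None):
    patients = pd.DataFrame(
        [("p1", "F", 1950, "A", "2010-01-01", "2020-01-01"),
         ("p2", "M", 1960, "A", "2010-01-01", "2020-01-01")],
        columns=["patient_id", "gender", "birth_year", "practice_id",
                 "reg_start", "reg_end"],
    )
    practices = pd.DataFrame(
        {"practice_id": ["A"], "list_size": [2], "anchor": [1]}
    )
    scr = pd.DataFrame(
        scr_rows if scr_rows is not None
        else [("p1", "2014-02-01", 0, 80.0)],
        columns=["patient_id", "test_date", "seq", "value_umol_l"],
    )
    adm = pd.DataFrame(
        adm_rows or [], columns=["patient_id", "admit_date", "discharge_date"]
    )
    return write_bundle(tmp_path, patients, practices, scr, adm)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def test_clean_bundle_has_empty_quarantine(tmp_path):
    paths = tiny_bundle(tmp_path)
    bundle = validate_bundle(*paths.values())
    assert bundle.quarantine.empty
    assert bundle.quality_log.empty


def test_bad_rows_are_quarantined_with_reasons(tmp_path):
    paths = tiny_bundle(
        tmp_path,
        scr_rows=[
            ("p1", "2014-02-01", 0, 80.0),
            ("p1", "2014-02-02", 0, -5.0),       # non-positive
            ("p1", "2014-02-03", 0, 9000.0),     # outside plausibility band
            ("ghost", "2014-02-04", 0, 90.0),    # unknown patient
            ("p2", "2014-02-05", 0, 70.0),
            ("p2", "2014-02-05", 0, 75.0),       # conflicting duplicate key
        ],
    )
    bundle = validate_bundle(*paths.values())
    reasons = set(zip(bundle.quarantine["patient_id"], bundle.quarantine["reason"]))
    assert ("p1", "non-positive") in reasons
    assert ("p1", "implausible") in reasons
    assert ("ghost", "orphan") in reasons
    assert ("p2", "conflicting_duplicate") in reasons
    assert len(bundle.scr) == 1  # only the clean row survives


def test_malformed_header_is_a_hard_error(tmp_path):
    paths = tiny_bundle(tmp_path)
    pd.DataFrame({"oops": [1]}).to_csv(paths["scr_results"], index=False)
    with pytest.raises(ValueError, match="malformed header"):
        validate_bundle(*paths.values())


def test_unparseable_date_reports_its_line(tmp_path):
    paths = tiny_bundle(
        tmp_path,
        scr_rows=[("p1", "2014-02-01", 0, 80.0),
                  ("p1", "not-a-date", 0, 82.0)],
    )
    with pytest.raises(ValueError, match="line 3"):
        validate_bundle(*paths.values())


def test_open_discharge_is_accepted(tmp_path):
    paths = tiny_bundle(tmp_path, adm_rows=[("p1", "2014-02-01", None)])
    bundle = validate_bundle(*paths.values())
    assert bundle.quarantine.empty
    assert pd.isna(bundle.admissions.loc[0, "discharge_date"])


# ---------------------------------------------------------------------------
# Report shapes
# ---------------------------------------------------------------------------

def cohort_frame(n, with_counts):
    pats = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "gender": ["F" if i % 2 else "M" for i in range(n)],
            "birth_year": [1950] * n,
        }
    )
    scr = pd.DataFrame(
        [(f"p{i}", "2014-01-01", 80.0) for i in range(with_counts) for _ in range(2)],
        columns=["patient_id", "test_date", "value_umol_l"],
    )
    return pats, scr


def test_demographic_report_row_percentages():
    pats, scr = cohort_frame(10, with_counts=3)
    rep = demographic_report(pats, scr, pd.DataFrame(columns=["patient_id"]),
                             OBS_START)
    total = rep[rep["group"] == "cohort"].iloc[0]
    assert total["n"] == 10
    assert total["pct_scr_2plus"] == pytest.approx(30.0)
    assert total["pct_scr_0_1"] == pytest.approx(70.0)
    assert total["alerts"] == 0
    # gender rows partition the cohort
    assert rep.loc[rep["group"] == "gender", "n"].sum() == 10
    assert rep.loc[rep["group"] == "age", "n"].sum() == 10


def test_alert_type_report_partition_and_percentages():
    classified = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "d"],
            "aki_type": ["CA_NOT_ADMITTED", "CA_ADMITTED_7D",
                         "CA_ON_ADMISSION", "HA"],
        }
    )
    rep = alert_type_report(classified, classified)
    by = rep.set_index("aki_type")
    assert (by.loc[["CA_NOT_ADMITTED", "CA_ADMITTED_7D", "CA_ON_ADMISSION",
                    "HA"], "all_pct"] == 25.0).all()
    assert by.loc["ALL_CA", "all_n"] == 3
    assert by.loc["ALL_CA", "all_n"] + by.loc["HA", "all_n"] == by.loc["TOTAL", "all_n"]


def test_all_hospital_alerts_report():
    classified = pd.DataFrame({"patient_id": ["a", "b"], "aki_type": ["HA", "HA"]})
    rep = alert_type_report(classified, classified).set_index("aki_type")
    assert rep.loc["HA", "all_pct"] == 100.0
    assert rep.loc["ALL_CA", "all_n"] == 0


def test_render_rounds_to_one_decimal_only_in_display():
    classified = pd.DataFrame(
        {"patient_id": list("abc"), "aki_type": ["HA", "HA", "CA_NOT_ADMITTED"]}
    )
    rep = alert_type_report(classified, classified)
    assert rep.set_index("aki_type").loc["HA", "all_pct"] == pytest.approx(200 / 3)
    assert "66.7" in render_report(rep)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sim_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    ds = generate(SimulationConfig(seed=5, n_patients=1200, n_practices=10))
    return ds, ds.write(out)


def run(paths, **kw):
    return run_pipeline(
        paths["patients"], paths["practices"], paths["scr_results"],
        paths["admissions"], STUDY_START, OBS_START, OBS_END, **kw,
    )


def test_pipeline_reports_are_mutually_consistent(sim_paths, tmp_path):
    _, paths = sim_paths
    result = run(paths, out_dir=tmp_path / "out")
    t2_total = result.table2[result.table2["group"] == "cohort"].iloc[0]
    t3 = result.table3.set_index("aki_type")
    assert t3.loc["TOTAL", "all_n"] == t2_total["alerts"] == len(result.alerts)
    assert t3.loc["TOTAL", "first_n"] == t2_total["patients_alerted"]
    assert t3.loc["TOTAL", "first_n"] == result.alerts["patient_id"].nunique()
    # percentages recomputed from raw counts match stored values
    if t3.loc["TOTAL", "all_n"]:
        recomputed = 100.0 * t3["all_n"] / t3.loc["TOTAL", "all_n"]
        assert recomputed.drop("TOTAL").equals(t3["all_pct"].drop("TOTAL"))
    for f in ("cohort.csv", "alerts.csv", "table2.csv", "table3.csv",
              "manifest.json", "quality_log.csv"):
        assert (tmp_path / "out" / f).exists()


def test_pipeline_manifest_is_reproducible(sim_paths):
    _, paths = sim_paths
    a = run(paths).manifest
    b = run(paths).manifest
    assert a == b


def test_alerts_csv_round_trips_exactly(sim_paths, tmp_path):
    _, paths = sim_paths
    result = run(paths, out_dir=tmp_path / "rt")
    written = pd.read_csv(tmp_path / "rt" / "alerts.csv")
    original = result.alerts.copy()
    original["test_date"] = original["test_date"].astype(str)
    written["test_date"] = written["test_date"].astype(str)
    pd.testing.assert_frame_equal(written, original, check_dtype=False)


def test_quarantined_rows_never_reach_detection(sim_paths, tmp_path):
    ds, _ = sim_paths
    scr = ds.scr_results.copy()
    poisoned = pd.concat(
        [scr, pd.DataFrame([{"patient_id": scr.iloc[0]["patient_id"],
                             "test_date": "2014-05-05", "seq": 9,
                             "value_umol_l": -40.0}])],
        ignore_index=True,
    )
    paths = write_bundle(tmp_path, ds.patients, ds.practices, poisoned,
                         ds.admissions)
    result = run(paths)
    assert result.manifest["counts"]["rows_quarantined"] == 1
    assert (result.bundle.scr["value_umol_l"] > 0).all()


def test_empty_cohort_gives_empty_reports(tmp_path):
    # viable practices but every patient is a minor -> empty cohort
    patients = pd.DataFrame(
        [(f"p{i}", "F", 2005, f"P{i % 4}", "2010-01-01", "2020-01-01")
         for i in range(8)],
        columns=["patient_id", "gender", "birth_year", "practice_id",
                 "reg_start", "reg_end"],
    )
    practices = pd.DataFrame(
        {"practice_id": [f"P{i}" for i in range(4)],
         "list_size": [2] * 4,
         "anchor": [1] * 4}
    )
    scr = pd.DataFrame(
        [(f"p{i}", "2014-02-01", 0, 80.0) for i in range(8)],
        columns=["patient_id", "test_date", "seq", "value_umol_l"],
    )
    adm = pd.DataFrame(columns=["patient_id", "admit_date", "discharge_date"])
    paths = write_bundle(tmp_path, patients, practices, scr, adm)
    result = run(paths)
    assert not result.cohort.included_patients
    assert result.alerts.empty
    assert result.table3.set_index("aki_type").loc["TOTAL", "all_n"] == 0
    assert (result.table2["n"] == 0).all()
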