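"""Shared fixtures: tiny typed claim-table builders and a hand-built
10-patient cohort whose attrition report and patient records are known by
hand-count."""

from __future__ import annotations

import pandas as pd
import pytest

from msrelapse.config import StudyConfig
from msrelapse.io import DX_COLS


def mk_medical(rows):
    """rows: (patient_id, start, end, setting, [dx...], proc_codes, paid_dollars)"""
    recs = []
    for pid, start, end, setting, dx, procs, paid in rows:
        dx = (list(dx) + [""] * 4)[:4]
        recs.append((pid, pd.Timestamp(start), pd.Timestamp(end), setting,
                     *dx, procs, int(round(paid * 100))))
    df = pd.DataFrame(recs, columns=["patient_id", "service_start", "service_end",
                                     "setting", *DX_COLS, "proc_codes", "paid_cents"])
    if df.empty:
        df = df.astype({"service_start": "datetime64[ns]", "service_end": "datetime64[ns]",
                        "paid_cents": "int64"})
    return df


def mk_pharmacy(rows):
    """rows: (patient_id, fill_date, drug_code, days_supply, paid_dollars)"""
    df = pd.DataFrame(
        [(pid, pd.Timestamp(d), drug, int(n), int(round(paid * 100)))
         for pid, d, drug, n, paid in rows],
        columns=["patient_id", "fill_date", "drug_code", "days_supply", "paid_cents"])
    if df.empty:
        df = df.astype({"fill_date": "datetime64[ns]", "days_supply": "int64",
                        "paid_cents": "int64"})
    return df


def mk_enrollment(rows):
    """rows: (patient_id, start, end, birth_year, sex, region, employment, plan)"""
    return pd.DataFrame(
        [(pid, pd.Timestamp(s), pd.Timestamp(e), by, sex, reg, emp, plan)
         for pid, s, e, by, sex, reg, emp, plan in rows],
        columns=["patient_id", "span_start", "span_end", "birth_year", "sex",
                 "region", "employment", "plan_type"])


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


def _fills(pid, drug, start, step, n, supply=30, paid=2000.0):
    d = pd.Timestamp(start)
    return [(pid, d + pd.Timedelta(days=step * k), drug, supply, paid) for k in range(n)]


@pytest.fixture(scope="session")
def attrition_fixture():
    """Ten crafted patients: two fail the diagnosis filter, one the enrollment
    filter, one the age filter; the six kept patients have hand-computed
    analysis rows."""
    med_rows = []
    # standard qualifying MS diagnoses for everyone except F01 (2009 only)
    # and F02 (no MS codes at all)
    for pid in ["F03", "F04", "F05", "F06", "F07", "F08", "F09", "F10"]:
        med_rows.append((pid, "2008-03-01", "2008-03-01", "outpatient", ["340"], "", 100.0))
    for pid in ["F01", "F03", "F04", "F05", "F06", "F07", "F08", "F09", "F10"]:
        med_rows.append((pid, "2009-03-01", "2009-03-01", "outpatient", ["340"], "", 100.0))
    med_rows.append(("F02", "2008-04-01", "2008-04-01", "outpatient", ["486"], "", 90.0))
    med_rows.append(("F02", "2009-04-01", "2009-04-01", "outpatient", ["486"], "", 90.0))

    # F03: two relapses (inpatient + outpatient/steroid), baseline ER visit,
    # follow-up MS hospitalization
    med_rows += [
        ("F03", "2009-02-01", "2009-02-04", "inpatient", ["340"], "", 8000.0),
        ("F03", "2009-06-01", "2009-06-01", "outpatient", ["340"], "", 150.0),
        ("F03", "2009-09-01", "2009-09-01", "er", ["786.50"], "", 500.0),
        ("F03", "2010-04-01", "2010-04-04", "inpatient", ["340"], "", 10000.0),
        ("F03", "2010-07-01", "2010-07-01", "outpatient", ["340"], "", 100.0),
    ]
    # F04: treatment-naive with an MS-symptom claim; starts DMT in follow-up
    med_rows += [
        ("F04", "2009-05-10", "2009-05-10", "outpatient", ["780.79"], "", 80.0),
        ("F04", "2010-03-01", "2010-03-01", "outpatient", ["340"], "", 60.0),
    ]
    # F05: one diabetes claim (Charlson weight 1)
    med_rows.append(("F05", "2009-04-01", "2009-04-01", "outpatient", ["250.01"], "", 120.0))
    # F06: switches to natalizumab (J-code) in follow-up; small follow-up claim
    med_rows += [
        ("F06", "2010-05-10", "2010-05-10", "outpatient", [], "J2323", 3000.0),
        ("F06", "2010-08-01", "2010-08-01", "outpatient", ["786.50"], "", 75.0),
    ]
    # F07: one outpatient relapse (MS secondary + steroid two days later)
    med_rows.append(("F07", "2009-03-10", "2009-03-10", "outpatient",
                     ["367.4", "340"], "", 140.0))

    pharm_rows = [
        ("F03", "2009-06-05", "methylprednisolone", 7, 20.0),
        ("F04", "2010-02-01", "glatiramer_acetate", 30, 2500.0),
        ("F07", "2009-03-12", "prednisone", 10, 15.0),
        ("F07", "2009-07-01", "glatiramer_acetate", 30, 2200.0),
    ]
    # F05: twelve 30-day glatiramer fills from 2009-01-05 (PDC 361/365), then
    # nothing -> run-out 2009-12-31, discontinuation
    pharm_rows += _fills("F05", "glatiramer_acetate", "2009-01-05", 30, 12)
    # F06: continuous interferon beta-1a fills through the censor date
    pharm_rows += _fills("F06", "interferon_beta_1a", "2009-01-01", 30, 25)

    enrol_rows = [
        ("F01", "2008-01-01", "2010-12-31", 1970, "female", "south", "employee", "ffs"),
        ("F02", "2008-01-01", "2010-12-31", 1960, "male", "west", "other", "ffs"),
        ("F03", "2008-01-01", "2010-12-31", 1970, "female", "south", "employee", "ffs"),
        ("F04", "2008-01-01", "2010-12-31", 1980, "male", "northeast", "other", "non_ffs"),
        ("F05", "2008-01-01", "2010-12-31", 1955, "female", "north_central", "employee", "ffs"),
        ("F06", "2008-01-01", "2010-12-31", 1948, "female", "west", "other", "ffs"),
        ("F07", "2008-01-01", "2010-12-31", 1975, "male", "south", "employee", "non_ffs"),
        # F08: 15-day enrollment hole in June 2010
        ("F08", "2008-01-01", "2010-05-31", 1970, "female", "south", "employee", "ffs"),
        ("F08", "2010-06-16", "2010-12-31", 1970, "female", "south", "employee", "ffs"),
        ("F09", "2008-01-01", "2010-12-31", 1962, "female", "northeast", "other", "missing"),
        ("F10", "2008-01-01", "2010-12-31", 1995, "male", "west", "other", "ffs"),
    ]
    return mk_medical(med_rows), mk_pharmacy(pharm_rows), mk_enrollment(enrol_rows)


# hand-counted expectations for the attrition fixture
EXPECTED_ATTRITION = [
    ("all_patients", 10),
    ("ms_dx_baseline_and_prior_year", 8),
    ("continuous_enrollment", 7),
    ("age_18_plus", 6),
]

EXPECTED_KEPT = ["F03", "F04", "F05", "F06", "F07", "F09"]

# hand-computed analysis rows for the kept patients (subset of columns)
EXPECTED_RECORDS = {
    # pid: (hra, relapse_count, age, cci, symptom, dmt_use, b_er, b_hosp,
    #       fu_er, fu_hosp, fu_ms_hosp, fu_cost_cents, subgroup, started,
    #       switched, discontinued)
    "F03": (1, 2, 39, 0.0, 0, 0, 1, 1, 0, 1, 1, 1010000, "naive", 0, 0, 0),
    "F04": (0, 0, 29, 0.0, 1, 0, 0, 0, 0, 0, 0, 6000, "naive", 1, 0, 0),
    "F05": (0, 0, 54, 1.0, 0, 1, 0, 0, 0, 0, 0, 0, "experienced", 0, 0, 1),
    "F06": (0, 0, 61, 0.0, 0, 1, 0, 0, 0, 0, 0, 7500, "experienced", 0, 1, 0),
    "F07": (0, 1, 34, 0.0, 0, 1, 0, 0, 0, 0, 0, 0, "other_dmt_user", 0, 0, 0),
    "F09": (0, 0, 47, 0.0, 0, 0, 0, 0, 0, 0, 0, 0, "naive", 0, 0, 0),
}
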