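"""Patient-level covariates and outcomes: the analysis-ready record table.

One row per cohort patient carrying the HRA exposure, Table-1-style baseline
covariates (demographics, Charlson comorbidity index, MS-symptom flag, DMT
use, prior-year utilization), follow-up utilization flags (all-cause and
MS-specific ER and hospitalization), and total follow-up non-DMT costs in
exact integer cents.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .config import ConfigError, StudyConfig

AGE_GROUPS = ["18-35", "36-45", "46-55", "56-65", "65+"]

RECORD_COLUMNS = [
    "patient_id", "hra", "relapse_count", "age", "age_group", "sex", "region",
    "employment", "plan_type", "cci", "any_ms_symptom", "any_dmt_use",
    "baseline_er", "baseline_hosp",
    "fu_allcause_er", "fu_allcause_hosp", "fu_ms_er", "fu_ms_hosp",
    "fu_cost_nondmt_cents", "subgroup", "started", "switched", "discontinued",
]


def age_group(age: int) -> str:
    """Table-1 age bins; '56-65' includes 65, '65+' is older than 65."""
    if age <= 35:
        return "18-35"
    if age <= 45:
        return "36-45"
    if age <= 55:
        return "46-55"
    if age <= 65:
        return "56-65"
    return "65+"


def _dx_long(medical: pd.DataFrame, window: tuple[date, date]) -> pd.DataFrame:
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sub = medical[(medical["service_start"] >= lo) & (medical["service_start"] <= hi)]
    parts = [sub[["patient_id", c]].rename(columns={c: "code"}) for c in ("dx1", "dx2", "dx3", "dx4")]
    long = pd.concat(parts, ignore_index=True)
    return long[long["code"] != ""]


def _match_prefix(codes: pd.Series, prefixes: list[str]) -> pd.Series:
    mask = pd.Series(False, index=codes.index)
    for p in prefixes:
        mask |= codes.str.startswith(p)
    return mask


def compute_cci(dx_codes, cci_map: dict, cci_weights: dict) -> float:
    """Charlson score from a patient's diagnosis codes.

    Each category counts once however many claims carry it; the score is the
    sum of the configured weights of the categories present. Longest matching
    prefix wins when prefixes nest.
    """
    cats: set[str] = set()
    prefixes = sorted(cci_map, key=len, reverse=True)
    for code in dx_codes:
        for p in prefixes:
            if str(code).startswith(p):
                cats.add(cci_map[p])
                break
    missing = [c for c in cats if c not in cci_weights]
    if missing:
        raise ConfigError(f"cci_weights missing categories: {sorted(missing)}")
    return float(sum(cci_weights[c] for c in cats))


def cci_by_patient(medical: pd.DataFrame, window: tuple[date, date],
                   config: StudyConfig) -> pd.Series:
    long = _dx_long(medical, window)
    scores = {pat: compute_cci(grp["code"], config.cci_map, config.cci_weights)
              for pat, grp in long.groupby("patient_id")}
    return pd.Series(scores, dtype=float, name="cci")


def flag_ms_symptoms(dx_codes, symptom_codes: dict) -> int:
    """1 iff any code falls in any symptom group (prefix match)."""
    prefixes = [p for group in symptom_codes.values() for p in group]
    return int(any(str(code).startswith(p) for code in dx_codes for p in prefixes))


def symptoms_by_patient(medical: pd.DataFrame, window: tuple[date, date],
                        config: StudyConfig) -> pd.Series:
    long = _dx_long(medical, window)
    prefixes = [p for group in config.symptom_codes.values() for p in group]
    hit = long[_match_prefix(long["code"], prefixes)]
    return pd.Series(1, index=pd.Index(hit["patient_id"].unique(), name="patient_id"),
                     name="any_ms_symptom", dtype="int64")


def flag_utilization(medical: pd.DataFrame, window: tuple[date, date],
                     scope: str, setting: str, config: StudyConfig) -> pd.Series:
    """Per-patient binary utilization flag.

    ``scope`` is ``all_cause`` or ``ms_specific``; ``setting`` is ``er`` or
    ``inpatient``. The MS-specific rule checks the diagnosis positions the
    config allows for that setting (default: primary-only for
    hospitalizations, primary-or-secondary for ER visits).
    """
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sub = medical[(medical["service_start"] >= lo) & (medical["service_start"] <= hi)
                  & (medical["setting"] == setting)]
    if scope == "ms_specific":
        rule = (config.ms_hosp_dx_positions if setting == "inpatient"
                else config.ms_er_dx_positions)
        cols = ["dx1"] if rule == "primary_only" else ["dx1", "dx2"]
        mask = pd.Series(False, index=sub.index)
        for c in cols:
            mask |= sub[c].str.startswith(config.ms_dx_prefix)
        sub = sub[mask]
    elif scope != "all_cause":
        raise ValueError(f"unknown scope {scope!r}")
    return pd.Series(1, index=pd.Index(sub["patient_id"].unique(), name="patient_id"),
                     dtype="int64")


def sum_nondmt_costs(medical: pd.DataFrame, pharmacy: pd.DataFrame,
                     window: tuple[date, date], config: StudyConfig) -> pd.Series:
    """Total paid amount per patient over ``window``, excluding DMT claims.

    Pharmacy claims with DMT drug codes and medical claims carrying a DMT
    J-code are excluded. Sums are exact integer cents.
    """
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    med = medical[(medical["service_start"] >= lo) & (medical["service_start"] <= hi)]
    if (med["paid_cents"] < 0).any() or (pharmacy["paid_cents"] < 0).any():
        raise ValueError("negative paid_amount encountered (claim reversals unsupported)")
    dmt_j = config.dmt_jcodes()
    keep_med = ~med["proc_codes"].map(
        lambda s: bool(dmt_j.intersection(s.split(";"))) if s else False)
    ph = pharmacy[(pharmacy["fill_date"] >= lo) & (pharmacy["fill_date"] <= hi)]
    keep_ph = ~ph["drug_code"].isin(config.dmt_pharmacy_codes())
    total = pd.concat([
        med.loc[keep_med, ["patient_id", "paid_cents"]],
        ph.loc[keep_ph, ["patient_id", "paid_cents"]],
    ]).groupby("patient_id")["paid_cents"].sum()
    total.name = "fu_cost_nondmt_cents"
    return total


def build_patient_records(cohort_ids: pd.Index, medical: pd.DataFrame,
                          pharmacy: pd.DataFrame, enrollment: pd.DataFrame,
                          relapse_counts: pd.Series, config: StudyConfig,
                          subgroups: pd.DataFrame | None = None,
                          patterns=None) -> pd.DataFrame:
    """Assemble one analysis row per cohort patient.

    ``relapse_counts`` is the baseline-year episode count (missing patients
    count 0). ``subgroups`` and ``patterns`` (a
    :class:`msrelapse.patterns.PatternOutcomes`) are optional; absent fields
    are filled with their neutral values.
    """
    ids = pd.Index(cohort_ids, name="patient_id")
    demo = enrollment.drop_duplicates("patient_id").set_index("patient_id")
    missing = ids.difference(demo.index)
    if len(missing):
        raise ValueError(f"patients missing from enrollment: {list(missing)[:5]}")

    base_w = config.baseline_window()
    fu_w = config.followup_window()
    counts = relapse_counts.reindex(ids, fill_value=0).astype("int64")

    def flag(scope, setting, window):
        return flag_utilization(medical, window, scope, setting, config).reindex(ids, fill_value=0)

    b_lo, b_hi = (pd.Timestamp(d) for d in base_w)
    dmt_ph = pharmacy[pharmacy["drug_code"].isin(config.dmt_pharmacy_codes())
                      & (pharmacy["fill_date"] >= b_lo) & (pharmacy["fill_date"] <= b_hi)]
    dmt_j = config.dmt_jcodes()
    dmt_med = medical[medical["proc_codes"].map(
        lambda s: bool(dmt_j.intersection(s.split(";"))) if s else False)
        & (medical["service_start"] >= b_lo) & (medical["service_start"] <= b_hi)]
    any_dmt = pd.Index(set(dmt_ph["patient_id"]) | set(dmt_med["patient_id"]))

    age = (config.baseline_year - demo.loc[ids, "birth_year"]).astype("int64")
    rec = pd.DataFrame({
        "patient_id": ids,
        "hra": counts.ge(config.hra_threshold).astype("int64").to_numpy(),
        "relapse_count": counts.to_numpy(),
        "age": age.to_numpy(),
        "age_group": [age_group(a) for a in age],
        "sex": demo.loc[ids, "sex"].to_numpy(),
        "region": demo.loc[ids, "region"].to_numpy(),
        "employment": demo.loc[ids, "employment"].to_numpy(),
        "plan_type": demo.loc[ids, "plan_type"].to_numpy(),
        "cci": cci_by_patient(medical, base_w, config).reindex(ids, fill_value=0.0).to_numpy(),
        "any_ms_symptom": symptoms_by_patient(medical, base_w, config).reindex(ids, fill_value=0).to_numpy(),
        "any_dmt_use": ids.isin(any_dmt).astype("int64"),
        "baseline_er": flag("all_cause", "er", base_w).to_numpy(),
        "baseline_hosp": flag("all_cause", "inpatient", base_w).to_numpy(),
        "fu_allcause_er": flag("all_cause", "er", fu_w).to_numpy(),
        "fu_allcause_hosp": flag("all_cause", "inpatient", fu_w).to_numpy(),
        "fu_ms_er": flag("ms_specific", "er", fu_w).to_numpy(),
        "fu_ms_hosp": flag("ms_specific", "inpatient", fu_w).to_numpy(),
        "fu_cost_nondmt_cents": sum_nondmt_costs(medical, pharmacy, fu_w, config)
                                .reindex(ids, fill_value=0).astype("int64").to_numpy(),
    })
    rec["subgroup"] = "none"
    if subgroups is not None:
        sg = subgroups.set_index("patient_id")["subgroup"]
        extra = sg.index.difference(ids)
        if len(extra):
            raise ValueError(f"subgroup assignment for non-cohort patients: {list(extra)[:5]}")
        rec["subgroup"] = sg.reindex(ids, fill_value="none").to_numpy()
    for name in ("started", "switched", "discontinued"):
        rec[name] = 0
        if patterns is not None:
            series = getattr(patterns, name)
            rec[name] = series.reindex(ids, fill_value=0).astype("int64").to_numpy()
    assert (rec["fu_ms_er"] <= rec["fu_allcause_er"]).all()
    assert (rec["fu_ms_hosp"] <= rec["fu_allcause_hosp"]).all()
    return rec[RECORD_COLUMNS]
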