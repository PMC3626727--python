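"""Cohort selection and treatment-experience subgrouping.

Main-cohort filters, applied in order with attrition logged per step:

(a) at least one claim with an MS diagnosis (any position) in the baseline
    year AND at least one in the prior year;
(b) continuous enrollment over every day of the baseline and follow-up years
    (administrative span breaks up to ``enrollment_gap_allowance`` days are
    bridged);
(c) age at the baseline year of at least ``min_age``.

Subgroups partition the main cohort: treatment-naïve (zero baseline DMT
claims), treatment-experienced (maximum single-drug PDC at or above the
threshold, default 80%), excluded_jcode (ABCR therapy billed through J-codes —
switches cannot be followed), and other_dmt_user (DMT-exposed below the PDC
bar; eligible for the sensitivity cohort, which takes every DMT-exposed
patient regardless of PDC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .config import ABCR_DRUGS, StudyConfig


@dataclass
class AttritionReport:
    """Ordered (filter label, patients remaining) pairs; counts non-increasing."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, label: str, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][1]:
            raise ValueError("attrition counts must be non-increasing")
        self.steps.append((label, int(n_remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_remaining"])


def _ms_dx_patients(medical: pd.DataFrame, window: tuple[date, date], prefix: str) -> set[str]:
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    in_window = medical[(medical["service_start"] >= lo) & (medical["service_start"] <= hi)]
    has_ms = pd.Series(False, index=in_window.index)
    for col in ("dx1", "dx2", "dx3", "dx4"):
        has_ms |= in_window[col].str.startswith(prefix)
    return set(in_window.loc[has_ms, "patient_id"])


def _continuously_enrolled(enrollment: pd.DataFrame, lo: date, hi: date,
                           allowance: int) -> set[str]:
    """Patients whose merged enrollment spans cover [lo, hi] without a gap
    longer than ``allowance`` days (spans are inclusive of both end dates)."""
    lo, hi = pd.Timestamp(lo), pd.Timestamp(hi)
    bridge = pd.Timedelta(days=allowance + 1)
    ok: set[str] = set()
    for pat, grp in enrollment.groupby("patient_id"):
        spans = grp.sort_values("span_start")
        merged: list[list[pd.Timestamp]] = []
        for s, e in zip(spans["span_start"], spans["span_end"]):
            if merged and s <= merged[-1][1] + bridge:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if any(a <= lo and b >= hi for a, b in merged):
            ok.add(pat)
    return ok


def select_main_cohort(medical: pd.DataFrame, enrollment: pd.DataFrame,
                       config: StudyConfig,
                       pharmacy: pd.DataFrame | None = None,
                       ) -> tuple[pd.Index, AttritionReport]:
    """Apply the selection filters; returns (patient ids, attrition report)."""
    universe = set(medical["patient_id"]) | set(enrollment["patient_id"])
    if pharmacy is not None:
        universe |= set(pharmacy["patient_id"])
    report = AttritionReport()
    report.add("all_patients", len(universe))

    with_dx = (_ms_dx_patients(medical, config.baseline_window(), config.ms_dx_prefix)
               & _ms_dx_patients(medical, config.prior_window(), config.ms_dx_prefix))
    kept = universe & with_dx
    report.add("ms_dx_baseline_and_prior_year", len(kept))

    lo = date(config.baseline_year, 1, 1)
    hi = date(config.followup_year, 12, 31)
    enrolled = _continuously_enrolled(enrollment[enrollment["patient_id"].isin(kept)],
                                      lo, hi, config.enrollment_gap_allowance)
    kept &= enrolled
    report.add("continuous_enrollment", len(kept))

    birth = enrollment.drop_duplicates("patient_id").set_index("patient_id")["birth_year"]
    age_ok = {p for p in kept if config.baseline_year - int(birth[p]) >= config.min_age}
    kept = age_ok
    report.add("age_18_plus", len(kept))
    return pd.Index(sorted(kept), name="patient_id"), report


def assign_subgroups(cohort_ids: pd.Index, dmt_claim_table: pd.DataFrame,
                     medical: pd.DataFrame, pdc_table: pd.DataFrame,
                     config: StudyConfig) -> pd.DataFrame:
    """Partition the cohort into naive / experienced / excluded_jcode / other_dmt_user.

    ``dmt_claim_table`` is a :func:`msrelapse.patterns.dmt_claims` table;
    ``pdc_table`` a (patient_id, drug, pdc) table over the baseline year.
    """
    lo, hi = (pd.Timestamp(d) for d in config.baseline_window())
    base = dmt_claim_table[(dmt_claim_table["date"] >= lo) & (dmt_claim_table["date"] <= hi)]
    base = base[base["patient_id"].isin(cohort_ids)]
    dmt_users = set(base["patient_id"])

    abcr_j = set(base[(base["source"] == "jcode")
                      & base["drug"].isin(ABCR_DRUGS)]["patient_id"])

    if config.pdc_rule == "union_all_dmt":
        union = compute_union_pdc(base, config)
        max_pdc = union.reindex(cohort_ids, fill_value=0.0)
    else:
        max_pdc = (pdc_table[pdc_table["patient_id"].isin(cohort_ids)]
                   .groupby("patient_id")["pdc"].max()
                   .reindex(cohort_ids, fill_value=0.0))

    rows = []
    for pat in cohort_ids:
        if pat not in dmt_users:
            sub = "naive"
        elif pat in abcr_j:
            sub = "excluded_jcode"
        elif max_pdc[pat] >= config.pdc_threshold:
            sub = "experienced"
        else:
            sub = "other_dmt_user"
        rows.append((pat, sub))
    return pd.DataFrame(rows, columns=["patient_id", "subgroup"])


def compute_union_pdc(baseline_dmt_claims: pd.DataFrame, config: StudyConfig) -> pd.Series:
    """Alternative PDC: union of covered days across every DMT."""
    from .patterns import compute_pdc
    period = config.baseline_window()
    return pd.Series({pat: compute_pdc(grp, period, config)
                      for pat, grp in baseline_dmt_claims.groupby("patient_id")},
                     name="pdc", dtype=float)


def select_sensitivity_cohort(subgroups: pd.DataFrame) -> pd.Index:
    """All DMT-exposed patients regardless of PDC (J-code-only ABCR still excluded)."""
    keep = subgroups[subgroups["subgroup"].isin(["experienced", "other_dmt_user"])]
    return pd.Index(sorted(keep["patient_id"]), name="patient_id")
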