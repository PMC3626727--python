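"""Proportion of days covered (PDC) and DMT treatment-pattern detection.

Drug exposure comes from two claim streams: pharmacy fills, covering
``[fill_date, fill_date + days_supply)``, and in-office J-code administrations
on medical claims, which carry no days supply and receive a configurable
imputed supply (default 30 days). PDC over a period is the size of the union
of covered days intersected with the period, divided by the period length —
overlapping fills never double-count (no stockpiling by default; a
shift-forward option is available).

Pattern events over the flexible follow-up window (index date through the
censor date):

* discontinuation — a gap of at least ``gap_days`` (default 60) between an
  index-drug supply run-out and the next index-drug claim, or between the
  final run-out and the censor date; dated at the run-out.
* switch — the first claim for a DMT other than the index drug.
* initiation — for treatment-naïve patients, the first DMT claim in follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import StudyConfig

PATTERN_COLUMNS = ["patient_id", "kind", "event_date", "from_drug", "to_drug"]


class DataError(ValueError):
    """Input claim data violates a precondition (e.g. non-positive supply)."""


def dmt_claims(pharmacy: pd.DataFrame, medical: pd.DataFrame,
               config: StudyConfig) -> pd.DataFrame:
    """Long table of DMT exposure claims: patient_id, drug, date, days_supply, source.

    Pharmacy fills are matched by drug code; medical claims by DMT J-codes
    (imputed ``jcode_days_supply``).
    """
    parts = []
    for drug, codes in config.dmt_codes.items():
        ph = pharmacy[pharmacy["drug_code"].isin(set(codes.get("pharmacy", [])))]
        if len(ph):
            if (ph["days_supply"] <= 0).any():
                raise DataError(f"non-positive days_supply on a {drug} fill")
            parts.append(pd.DataFrame({
                "patient_id": ph["patient_id"], "drug": drug,
                "date": ph["fill_date"], "days_supply": ph["days_supply"],
                "source": "pharmacy"}))
        jcodes = set(codes.get("jcode", []))
        if jcodes and len(medical):
            has_j = medical["proc_codes"].map(
                lambda s: bool(jcodes.intersection(s.split(";"))) if s else False)
            mj = medical[has_j]
            if len(mj):
                parts.append(pd.DataFrame({
                    "patient_id": mj["patient_id"], "drug": drug,
                    "date": mj["service_start"],
                    "days_supply": config.jcode_days_supply,
                    "source": "jcode"}))
    if not parts:
        return pd.DataFrame({
            "patient_id": pd.Series(dtype=str), "drug": pd.Series(dtype=str),
            "date": pd.Series(dtype="datetime64[ns]"),
            "days_supply": pd.Series(dtype="int64"), "source": pd.Series(dtype=str)})
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["patient_id", "date", "drug"], kind="mergesort").reset_index(drop=True)


def _coverage_intervals(starts: np.ndarray, supplies: np.ndarray,
                        stockpiling: bool) -> list[tuple[np.datetime64, np.datetime64]]:
    """Merge fills into disjoint half-open coverage intervals [start, end)."""
    order = np.argsort(starts, kind="mergesort")
    starts, supplies = starts[order], supplies[order]
    intervals: list[list] = []
    for s, n in zip(starts, supplies):
        e = s + np.timedelta64(int(n), "D")
        if stockpiling and intervals and s < intervals[-1][1]:
            # shift the new fill to start at the current run-out
            s = intervals[-1][1]
            e = s + np.timedelta64(int(n), "D")
        if intervals and s <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], e)
        else:
            intervals.append([s, e])
    return [(a, b) for a, b in intervals]


def compute_pdc(fills: pd.DataFrame, period: tuple[date, date],
                config: StudyConfig | None = None) -> float:
    """PDC = |union of covered days ∩ period| / |period|.

    ``fills`` needs columns ``date`` and ``days_supply`` (one drug, one
    patient). The period is inclusive of both end dates; supply extending past
    the period end is truncated.
    """
    lo = np.datetime64(pd.Timestamp(period[0]), "D")
    hi = np.datetime64(pd.Timestamp(period[1]) + pd.Timedelta(days=1), "D")  # exclusive
    denom = int((hi - lo) / np.timedelta64(1, "D"))
    if denom <= 0:
        raise ValueError("empty PDC period")
    if len(fills) == 0:
        return 0.0
    if (fills["days_supply"] <= 0).any():
        raise DataError("non-positive days_supply in PDC input")
    starts = fills["date"].to_numpy().astype("datetime64[D]")
    stock = bool(config.stockpiling) if config is not None else False
    covered = 0
    for a, b in _coverage_intervals(starts, fills["days_supply"].to_numpy(), stock):
        a, b = max(a, lo), min(b, hi)
        if b > a:
            covered += int((b - a) / np.timedelta64(1, "D"))
    return covered / denom


def compute_pdc_table(claims: pd.DataFrame, period: tuple[date, date],
                      config: StudyConfig) -> pd.DataFrame:
    """Per (patient, drug) PDC over ``period`` from a :func:`dmt_claims` table."""
    rows = [(pat, drug, compute_pdc(grp, period, config))
            for (pat, drug), grp in claims.groupby(["patient_id", "drug"], sort=True)]
    return pd.DataFrame(rows, columns=["patient_id", "drug", "pdc"])


def identify_index_dmt(baseline_claims: pd.DataFrame) -> tuple[str, pd.Timestamp]:
    """The index DMT: drug of the latest baseline-year DMT claim.

    Ties on the same date break by longest days supply, then lexicographically
    smallest drug name. Returns ``(drug, index_date)``.
    """
    if len(baseline_claims) == 0:
        raise ValueError("identify_index_dmt requires at least one baseline DMT claim")
    last = baseline_claims[baseline_claims["date"] == baseline_claims["date"].max()]
    last = last.sort_values(["days_supply", "drug"], ascending=[False, True], kind="mergesort")
    row = last.iloc[0]
    return str(row["drug"]), pd.Timestamp(row["date"])


def detect_discontinuation(index_claims: pd.DataFrame, config: StudyConfig) -> dict | None:
    """First qualifying supply gap for the index drug.

    ``index_claims`` holds the patient's index-drug claims (any source).
    Returns a pattern-event dict with ``kind`` in {``discontinuation``,
    ``censored``}; the event date is the run-out date that opens the gap.
    """
    if len(index_claims) == 0:
        raise ValueError("detect_discontinuation requires index-drug claims")
    censor = np.datetime64(pd.Timestamp(config.censor_date), "D")
    pat = index_claims["patient_id"].iloc[0]
    drug = index_claims["drug"].iloc[0]
    starts = index_claims["date"].to_numpy().astype("datetime64[D]")
    runs = _coverage_intervals(starts, index_claims["days_supply"].to_numpy(),
                               config.stockpiling)
    gap = np.timedelta64(config.gap_days, "D")
    for (a, runout), nxt in zip(runs, runs[1:] + [None]):
        if runout > censor:
            break
        next_start = nxt[0] if nxt is not None else censor
        if next_start - runout >= gap:
            return {"patient_id": pat, "kind": "discontinuation",
                    "event_date": pd.Timestamp(runout), "from_drug": drug, "to_drug": ""}
    return {"patient_id": pat, "kind": "censored", "event_date": pd.Timestamp(censor),
            "from_drug": drug, "to_drug": ""}


def detect_switch(all_claims: pd.DataFrame, index_drug: str,
                  index_date: pd.Timestamp, config: StudyConfig) -> dict | None:
    """First claim for a DMT other than the index drug after the index date."""
    censor = pd.Timestamp(config.censor_date)
    other = all_claims[(all_claims["drug"] != index_drug)
                       & (all_claims["date"] > index_date)
                       & (all_claims["date"] <= censor)]
    if other.empty:
        return None
    other = other.sort_values(["date", "drug"], kind="mergesort")
    row = other.iloc[0]
    return {"patient_id": row["patient_id"], "kind": "switch",
            "event_date": pd.Timestamp(row["date"]),
            "from_drug": index_drug, "to_drug": str(row["drug"])}


def detect_initiation(patient_claims: pd.DataFrame, config: StudyConfig) -> dict | None:
    """First DMT claim in follow-up for a treatment-naïve patient."""
    if patient_claims.empty:
        return None
    b_lo, b_hi = (pd.Timestamp(d) for d in config.baseline_window())
    if ((patient_claims["date"] >= b_lo) & (patient_claims["date"] <= b_hi)).any():
        raise ValueError("naive patient has a baseline-year DMT claim: "
                         f"{patient_claims['patient_id'].iloc[0]}")
    censor = pd.Timestamp(config.censor_date)
    fu = patient_claims[(patient_claims["date"] > b_hi) & (patient_claims["date"] <= censor)]
    if fu.empty:
        return None
    fu = fu.sort_values(["date", "drug"], kind="mergesort")
    row = fu.iloc[0]
    return {"patient_id": row["patient_id"], "kind": "initiation",
            "event_date": pd.Timestamp(row["date"]), "from_drug": "",
            "to_drug": str(row["drug"])}


@dataclass
class PatternOutcomes:
    """Binary treatment-pattern outcomes plus the event table."""

    events: pd.DataFrame          # PATTERN_COLUMNS
    started: pd.Series            # naive patients
    switched: pd.Series           # experienced (or sensitivity) patients
    discontinued: pd.Series
    index_dmt: pd.Series


def detect_patterns(claims: pd.DataFrame, naive_ids, exposed_ids,
                    config: StudyConfig) -> PatternOutcomes:
    """Run initiation/switch/discontinuation detection over a cohort.

    ``claims`` is a :func:`dmt_claims` table for all patients. Switch and
    discontinuation are computed independently over ``exposed_ids`` (patients
    with a baseline index DMT); initiation over ``naive_ids``.
    """
    naive_ids = pd.Index(naive_ids, name="patient_id")
    exposed_ids = pd.Index(exposed_ids, name="patient_id")
    by_pat = {p: g for p, g in claims.groupby("patient_id")}
    b_lo, b_hi = (pd.Timestamp(d) for d in config.baseline_window())

    rows, started, switched, discontinued, index_dmt = [], {}, {}, {}, {}
    for pat in naive_ids:
        ev = detect_initiation(by_pat.get(pat, claims.iloc[0:0]), config)
        started[pat] = int(ev is not None)
        if ev:
            rows.append(ev)
    for pat in exposed_ids:
        grp = by_pat.get(pat)
        if grp is None:
            raise ValueError(f"patient {pat} has no DMT claims but is DMT-exposed")
        base = grp[(grp["date"] >= b_lo) & (grp["date"] <= b_hi)]
        drug, idx_date = identify_index_dmt(base)
        index_dmt[pat] = drug
        sw = detect_switch(grp, drug, idx_date, config)
        switched[pat] = int(sw is not None)
        if sw:
            rows.append(sw)
        idx_claims = grp[(grp["drug"] == drug) & (grp["date"] <= pd.Timestamp(config.censor_date))]
        dc = detect_discontinuation(idx_claims, config)
        discontinued[pat] = int(dc is not None and dc["kind"] == "discontinuation")
        if dc:
            rows.append(dc)
    events = (pd.DataFrame(rows, columns=PATTERN_COLUMNS) if rows
              else pd.DataFrame(columns=PATTERN_COLUMNS))
    if len(events):
        events = events.sort_values(["patient_id", "event_date", "kind"],
                                    kind="mergesort").reset_index(drop=True)
    return PatternOutcomes(
        events=events,
        started=pd.Series(started, dtype="int64", name="started").reindex(naive_ids, fill_value=0),
        switched=pd.Series(switched, dtype="int64", name="switched").reindex(exposed_ids, fill_value=0),
        discontinued=pd.Series(discontinued, dtype="int64", name="discontinued").reindex(exposed_ids, fill_value=0),
        index_dmt=pd.Series(index_dmt, name="index_dmt").reindex(exposed_ids, fill_value=""),
    )
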