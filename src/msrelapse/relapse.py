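"""Claims-based relapse detection and high-relapse-activity (HRA) classification.

A relapse is inferred from claims as either

1. an inpatient stay carrying an MS diagnosis (ICD-9-CM 340.xx) in the primary
   position, dated at admission, or
2. an outpatient or ER visit with an MS code in the primary or secondary
   position together with a qualifying corticosteroid claim (pharmacy fill or
   medical J-code) dated on the day of the visit or within
   ``steroid_window_days`` (default 7) after it.

Candidate events closer together than a ``clean_period_days`` (default 30)
event-free interval are merged into a single relapse episode; under the default
``chain`` rule an event opens a new episode only when it falls at least the
clean period after the *previous* event, so long chains collapse into one
episode. Patients with at least ``hra_threshold`` (default 2) episodes starting
in the baseline year form the HRA cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .config import ConfigError, StudyConfig

INPATIENT_MS_PRIMARY = "inpatient_ms_primary"
OUTPATIENT_MS_PLUS_STEROID = "outpatient_ms_plus_steroid"

EVENT_COLUMNS = ["patient_id", "event_date", "event_type", "source_claim_refs"]
EPISODE_COLUMNS = ["patient_id", "start_date", "end_date", "n_events", "severity", "event_dates"]


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": pd.Series(dtype=str),
        "event_date": pd.Series(dtype="datetime64[ns]"),
        "event_type": pd.Series(dtype=str),
        "source_claim_refs": pd.Series(dtype=object),
    })


def _has_ms_code(df: pd.DataFrame, prefix: str, positions: list[str]) -> pd.Series:
    mask = pd.Series(False, index=df.index)
    for col in positions:
        mask |= df[col].str.startswith(prefix)
    return mask


def _steroid_claims(medical: pd.DataFrame, pharmacy: pd.DataFrame,
                    config: StudyConfig) -> pd.DataFrame:
    """All qualifying corticosteroid claims: (patient_id, date, ref)."""
    pharm_codes = set(config.steroid_codes.get("pharmacy", []))
    jcodes = set(config.steroid_codes.get("jcode", []))
    parts = []
    ph = pharmacy[pharmacy["drug_code"].isin(pharm_codes)]
    if len(ph):
        parts.append(pd.DataFrame({
            "patient_id": ph["patient_id"],
            "date": ph["fill_date"],
            "ref": "pharmacy:" + ph.index.astype(str),
        }))
    if jcodes:
        has_j = medical["proc_codes"].map(
            lambda s: bool(jcodes.intersection(s.split(";"))) if s else False)
        mj = medical[has_j]
        if len(mj):
            parts.append(pd.DataFrame({
                "patient_id": mj["patient_id"],
                "date": mj["service_start"],
                "ref": "medical:" + mj.index.astype(str),
            }))
    if not parts:
        return pd.DataFrame(columns=["patient_id", "date", "ref"])
    return pd.concat(parts, ignore_index=True)


def find_candidate_events(medical: pd.DataFrame, pharmacy: pd.DataFrame,
                          config: StudyConfig) -> pd.DataFrame:
    """Detect candidate relapse events from typed claims.

    Returns one row per (patient, date, type), sorted by patient then date.
    Inpatient events are dated at admission; outpatient/ER events at the
    visit. Each steroid claim can qualify at most one visit — the earliest
    visit within its look-back window — so one fill is never spent on several
    clustered visits.
    """
    if not (config.steroid_codes.get("pharmacy") or config.steroid_codes.get("jcode")):
        raise ConfigError("steroid code list is empty while the outpatient rule is enabled")
    prefix = config.ms_dx_prefix

    inpt = medical[(medical["setting"] == "inpatient")
                   & medical["dx1"].str.startswith(prefix)]
    inpt_events = pd.DataFrame({
        "patient_id": inpt["patient_id"],
        "event_date": inpt["service_start"],
        "event_type": INPATIENT_MS_PRIMARY,
        "source_claim_refs": ("medical:" + inpt.index.astype(str)).map(lambda r: (r,)),
    })

    visits = medical[medical["setting"].isin(["outpatient", "er"])
                     & _has_ms_code(medical, prefix, ["dx1", "dx2"])]
    steroids = _steroid_claims(medical, pharmacy, config)

    out_rows: list[tuple] = []
    window = pd.Timedelta(days=config.steroid_window_days)
    if len(visits) and len(steroids):
        vis_by_pat = {p: g for p, g in visits.groupby("patient_id")}
        for pat, sgrp in steroids.groupby("patient_id"):
            vgrp = vis_by_pat.get(pat)
            if vgrp is None:
                continue
            vdates = vgrp["service_start"].sort_values()
            varr = vdates.to_numpy()
            qualified: dict[np.datetime64, list[str]] = {}
            for sdate, sref in zip(sgrp["date"], sgrp["ref"]):
                lo = np.searchsorted(varr, np.datetime64(sdate - window))
                hi = np.searchsorted(varr, np.datetime64(sdate), side="right")
                if lo < hi:
                    qualified.setdefault(varr[lo], []).append(sref)
            for vdate, srefs in qualified.items():
                claim_refs = tuple(
                    "medical:" + vgrp.index[vgrp["service_start"] == vdate].astype(str)
                ) + tuple(srefs)
                out_rows.append((pat, pd.Timestamp(vdate),
                                 OUTPATIENT_MS_PLUS_STEROID, claim_refs))
    out_events = pd.DataFrame(out_rows, columns=EVENT_COLUMNS) if out_rows else _empty_events()

    events = pd.concat([inpt_events, out_events], ignore_index=True)
    if events.empty:
        return _empty_events()
    # one event per (patient, date, type); claims splitting an encounter
    # across lines collapse here
    events = (events.groupby(["patient_id", "event_date", "event_type"], as_index=False)
              .agg(source_claim_refs=("source_claim_refs",
                                      lambda refs: tuple(r for t in refs for r in t))))
    return events.sort_values(["patient_id", "event_date", "event_type"]).reset_index(drop=True)


def merge_into_episodes(events: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Merge per-patient candidate events into relapse episodes.

    Events must arrive sorted by patient and date (the postcondition of
    :func:`find_candidate_events`). Severity is ``inpatient_involved`` when any
    contributing event is inpatient, else ``outpatient_only``.
    """
    rows = []
    clean = config.clean_period_days
    for pat, grp in events.groupby("patient_id", sort=True):
        dates = grp["event_date"].to_numpy()
        if np.any(np.diff(dates) < np.timedelta64(0, "ns")):
            raise RuntimeError(f"events for patient {pat} are not sorted by date")
        types = grp["event_type"].to_numpy()
        start_idx = 0
        anchor = dates[0]
        for i in range(1, len(dates) + 1):
            gap_ok = i < len(dates) and (dates[i] - anchor) < np.timedelta64(clean, "D")
            if gap_ok:
                if config.episode_rule == "chain":
                    anchor = dates[i]
                continue
            seg_dates = dates[start_idx:i]
            seg_types = types[start_idx:i]
            severity = ("inpatient_involved" if (seg_types == INPATIENT_MS_PRIMARY).any()
                        else "outpatient_only")
            rows.append((pat, pd.Timestamp(seg_dates[0]), pd.Timestamp(seg_dates[-1]),
                         len(seg_dates), severity,
                         ";".join(pd.Timestamp(d).strftime("%Y-%m-%d") for d in seg_dates)))
            if i < len(dates):
                start_idx = i
                anchor = dates[i]
    if not rows:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def count_relapses(episodes: pd.DataFrame, window: tuple[date, date]) -> pd.Series:
    """Episodes per patient whose start date lies inside ``window`` (inclusive)."""
    lo, hi = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if lo > hi:
        raise ValueError("window start after window end")
    if episodes.empty:
        return pd.Series(dtype="int64", name="relapse_count")
    inside = episodes[(episodes["start_date"] >= lo) & (episodes["start_date"] <= hi)]
    counts = inside.groupby("patient_id").size().astype("int64")
    counts.name = "relapse_count"
    return counts


def classify_hra(relapse_count: int | pd.Series, config: StudyConfig):
    """``hra`` iff the baseline-year relapse count reaches ``hra_threshold``."""
    if isinstance(relapse_count, pd.Series):
        return relapse_count.ge(config.hra_threshold).map({True: "hra", False: "non_hra"})
    if relapse_count < 0:
        raise ValueError("relapse_count must be non-negative")
    return "hra" if relapse_count >= config.hra_threshold else "non_hra"


@dataclass
class RelapseSummary:
    """Per-patient relapse counts and HRA status over the baseline year."""

    counts: pd.Series
    hra: pd.Series

    @classmethod
    def from_claims(cls, medical, pharmacy, config: StudyConfig,
                    patient_ids=None) -> "RelapseSummary":
        events = find_candidate_events(medical, pharmacy, config)
        episodes = merge_into_episodes(events, config)
        counts = count_relapses(episodes, config.baseline_window())
        if patient_ids is not None:
            counts = counts.reindex(pd.Index(patient_ids, name="patient_id"), fill_value=0)
        return cls(counts=counts, hra=classify_hra(counts, config))
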