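"""Relapse event detection, episode merging and HRA classification."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from msrelapse.config import ConfigError, StudyConfig
from msrelapse.relapse import (INPATIENT_MS_PRIMARY, OUTPATIENT_MS_PLUS_STEROID,
                               classify_hra, count_relapses, find_candidate_events,
                               merge_into_episodes)

from conftest import mk_medical, mk_pharmacy
from oracles import fixpoint_merge


def events_df(pid, days, base="2009-01-01", event_type=OUTPATIENT_MS_PLUS_STEROID):
    base = pd.Timestamp(base)
    return pd.DataFrame({
        "patient_id": pid,
        "event_date": [base + pd.Timedelta(days=d) for d in sorted(days)],
        "event_type": event_type,
        "source_claim_refs": [("x",)] * len(days),
    })


class TestCandidateEvents:
    def test_inpatient_ms_primary_dated_at_admission(self, config):
        med = mk_medical([("P1", "2009-03-01", "2009-03-06", "inpatient", ["340"], "", 9000.0)])
        ev = find_candidate_events(med, mk_pharmacy([]), config)
        assert len(ev) == 1
        assert ev.loc[0, "event_type"] == INPATIENT_MS_PRIMARY
        assert ev.loc[0, "event_date"] == pd.Timestamp("2009-03-01")

    def test_inpatient_requires_primary_position(self, config):
        med = mk_medical([("P1", "2009-03-01", "2009-03-06", "inpatient",
                           ["486", "340"], "", 9000.0)])
        assert find_candidate_events(med, mk_pharmacy([]), config).empty

    @pytest.mark.parametrize("fill_date,expected", [
        ("2009-05-10", 1),   # day of visit
        ("2009-05-15", 1),   # 5 days after, inside the 7-day window
        ("2009-05-17", 1),   # exactly 7 days after (inclusive)
        ("2009-05-20", 0),   # 10 days after, outside
        ("2009-05-08", 0),   # before the visit never qualifies
    ])
    def test_steroid_window_day_of_or_within_seven_days_after(self, config, fill_date, expected):
        med = mk_medical([("P1", "2009-05-10", "2009-05-10", "outpatient",
                           ["367.4", "340"], "", 150.0)])
        ph = mk_pharmacy([("P1", fill_date, "methylprednisolone", 7, 20.0)])
        ev = find_candidate_events(med, ph, config)
        assert len(ev) == expected
        if expected:
            assert ev.loc[0, "event_type"] == OUTPATIENT_MS_PLUS_STEROID
            assert ev.loc[0, "event_date"] == pd.Timestamp("2009-05-10")

    def test_er_visit_with_steroid_jcode_claim_qualifies(self, config):
        med = mk_medical([
            ("P1", "2009-05-10", "2009-05-10", "er", ["340"], "", 500.0),
            ("P1", "2009-05-12", "2009-05-12", "outpatient", [], "J2920", 60.0),
        ])
        ev = find_candidate_events(med, mk_pharmacy([]), config)
        assert len(ev) == 1 and ev.loc[0, "event_date"] == pd.Timestamp("2009-05-10")

    def test_one_steroid_qualifies_only_the_earliest_visit(self, config):
        med = mk_medical([
            ("P1", "2009-05-10", "2009-05-10", "outpatient", ["340"], "", 100.0),
            ("P1", "2009-05-12", "2009-05-12", "outpatient", ["340"], "", 100.0),
        ])
        ph = mk_pharmacy([("P1", "2009-05-13", "prednisone", 7, 10.0)])
        ev = find_candidate_events(med, ph, config)
        assert len(ev) == 1
        assert ev.loc[0, "event_date"] == pd.Timestamp("2009-05-10")

    def test_duplicate_claims_on_one_date_deduplicate(self, config):
        med = mk_medical([("P1", "2009-03-01", "2009-03-03", "inpatient", ["340"], "", 1.0)] * 3)
        ev = find_candidate_events(med, mk_pharmacy([]), config)
        assert len(ev) == 1

    def test_empty_steroid_list_is_a_config_error(self):
        cfg = StudyConfig()
        cfg.steroid_codes = {"pharmacy": [], "jcode": []}
        with pytest.raises(ConfigError):
            find_candidate_events(mk_medical([]), mk_pharmacy([]), cfg)

    def test_shift_invariance(self, config):
        med = mk_medical([
            ("P1", "2009-02-01", "2009-02-03", "inpatient", ["340"], "", 1.0),
            ("P1", "2009-04-01", "2009-04-01", "outpatient", ["340"], "", 1.0),
        ])
        ph = mk_pharmacy([("P1", "2009-04-03", "prednisone", 7, 1.0)])
        base = find_candidate_events(med, ph, config)
        k = 13
        med2, ph2 = med.copy(), ph.copy()
        for c in ("service_start", "service_end"):
            med2[c] += pd.Timedelta(days=k)
        ph2["fill_date"] += pd.Timedelta(days=k)
        shifted = find_candidate_events(med2, ph2, config)
        assert ((shifted["event_date"] - base["event_date"]) == pd.Timedelta(days=k)).all()


class TestEpisodeMerging:
    @pytest.mark.parametrize("days,expected", [
        ([0, 20], 1),          # gap 20 < 30: one episode
        ([0, 40], 2),          # clean period satisfied
        ([0, 25, 50], 1),      # chain-merge even though 50-0 > 30
        ([], 0),
        ([0, 29], 1),
        ([0, 30], 2),          # exactly the clean period starts a new episode
    ])
    def test_chain_merge_episode_counts(self, config, days, expected):
        ep = merge_into_episodes(events_df("P1", days), config)
        assert len(ep) == expected

    def test_start_to_start_alternative_rule(self):
        cfg = StudyConfig(episode_rule="start_to_start")
        ep = merge_into_episodes(events_df("P1", [0, 25, 50]), cfg)
        assert len(ep) == 2  # 50 is >= 30 days from the episode start at 0

    def test_severity_inpatient_involved_when_any_event_inpatient(self, config):
        ev = pd.concat([events_df("P1", [0]),
                        events_df("P1", [10], event_type=INPATIENT_MS_PRIMARY)])
        ev = ev.sort_values("event_date").reset_index(drop=True)
        ep = merge_into_episodes(ev, config)
        assert len(ep) == 1 and ep.loc[0, "severity"] == "inpatient_involved"

    def test_matches_fixpoint_oracle_on_random_event_sets(self, config):
        rng = np.random.default_rng(11)
        for _ in range(200):
            days = sorted(rng.choice(365, size=rng.integers(1, 9), replace=False))
            ep = merge_into_episodes(events_df("P1", days), config)
            oracle = fixpoint_merge(list(days), config.clean_period_days)
            assert len(ep) == len(oracle)
            base = pd.Timestamp("2009-01-01")
            got = [((s - base).days, (e - base).days)
                   for s, e in zip(ep["start_date"], ep["end_date"])]
            assert got == oracle

    def test_adding_one_event_changes_count_by_at_most_one(self, config):
        rng = np.random.default_rng(5)
        for _ in range(100):
            days = sorted(rng.choice(365, size=6, replace=False))
            n_before = len(merge_into_episodes(events_df("P1", days[:-1]), config))
            n_after = len(merge_into_episodes(events_df("P1", days), config))
            assert abs(n_after - n_before) <= 1

    def test_unsorted_events_rejected(self, config):
        ev = events_df("P1", [0, 10])
        ev["event_date"] = list(ev["event_date"])[::-1]  # descending dates
        with pytest.raises(RuntimeError, match="sorted"):
            merge_into_episodes(ev, config)


class TestCountingAndClassification:
    def test_counts_episodes_by_start_date_attribution(self, config):
        ev = events_df("P1", [0, 16], base="2008-12-20")  # spans the year boundary
        ep = merge_into_episodes(ev, config)
        assert len(ep) == 1
        counts = count_relapses(ep, (date(2009, 1, 1), date(2009, 12, 31)))
        assert counts.get("P1", 0) == 0  # attributed to 2008 by start date
        assert count_relapses(ep, (date(2008, 1, 1), date(2008, 12, 31)))["P1"] == 1

    def test_count_within_window_inclusive(self, config):
        ep = merge_into_episodes(events_df("P1", [31, 212]), config)
        counts = count_relapses(ep, (date(2009, 1, 1), date(2009, 12, 31)))
        assert counts["P1"] == 2

    def test_empty_episodes_count_zero(self, config):
        counts = count_relapses(merge_into_episodes(events_df("P1", []), config),
                                (date(2009, 1, 1), date(2009, 12, 31)))
        assert len(counts) == 0

    @pytest.mark.parametrize("count,expected", [(0, "non_hra"), (1, "non_hra"),
                                                (2, "hra"), (5, "hra")])
    def test_hra_threshold_is_two_or_more(self, config, count, expected):
        assert classify_hra(count, config) == expected

    def test_negative_count_rejected(self, config):
        with pytest.raises(ValueError):
            classify_hra(-1, config)
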