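"""PDC computation and treatment-pattern (index/switch/discontinue/start) detection."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msrelapse.config import StudyConfig
from msrelapse.patterns import (DataError, compute_pdc, detect_discontinuation,
                                detect_initiation, detect_switch, dmt_claims,
                                identify_index_dmt)

from conftest import mk_medical, mk_pharmacy
from oracles import enumerate_covered_days

YEAR_2009 = (date(2009, 1, 1), date(2009, 12, 31))


def fills_df(rows, pid="P1", drug="glatiramer_acetate"):
    """rows: (date, days_supply)"""
    return pd.DataFrame({
        "patient_id": pid,
        "drug": drug,
        "date": [pd.Timestamp(d) for d, _ in rows],
        "days_supply": [n for _, n in rows],
        "source": "pharmacy",
    })


class TestPdc:
    def test_single_90_day_fill(self):
        pdc = compute_pdc(fills_df([("2009-01-01", 90)]), YEAR_2009)
        assert pdc == pytest.approx(90 / 365)

    def test_no_fills_is_zero(self):
        assert compute_pdc(fills_df([]), YEAR_2009) == 0.0

    def test_overlapping_duplicate_fills_do_not_double_count(self):
        pdc = compute_pdc(fills_df([("2009-03-01", 30), ("2009-03-01", 30)]), YEAR_2009)
        assert pdc == pytest.approx(30 / 365)

    def test_supply_past_period_end_is_truncated(self):
        pdc = compute_pdc(fills_df([("2009-12-02", 90)]), YEAR_2009)
        assert pdc == pytest.approx(30 / 365)

    def test_pdc_080_meets_the_inclusive_threshold(self, config):
        pdc = compute_pdc(fills_df([("2009-01-01", 292)]), YEAR_2009)
        assert pdc == pytest.approx(292 / 365)
        assert pdc >= config.pdc_threshold

    def test_non_positive_supply_is_a_data_error(self):
        bad = fills_df([("2009-01-01", 30)])
        bad.loc[0, "days_supply"] = 0
        with pytest.raises(DataError):
            compute_pdc(bad, YEAR_2009)

    def test_stockpiling_shifts_overlapping_fills_forward(self):
        cfg = StudyConfig(stockpiling=True)
        pdc = compute_pdc(fills_df([("2009-03-01", 30), ("2009-03-15", 30)]), YEAR_2009, cfg)
        assert pdc == pytest.approx(60 / 365)

    def test_matches_day_enumeration_oracle_on_random_fill_sets(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            rows = [(date(2009, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365))),
                     int(rng.integers(1, 120))) for _ in range(n)]
            got = compute_pdc(fills_df(rows), YEAR_2009)
            days = [((pd.Timestamp(d) - pd.Timestamp("2009-01-01")).days, s) for d, s in rows]
            assert got == pytest.approx(enumerate_covered_days(days, 365) / 365)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 364), st.integers(1, 90)),
                    min_size=0, max_size=6))
    def test_pdc_in_unit_interval_and_monotone_in_added_fills(self, fills):
        rows = [(date(2009, 1, 1) + pd.Timedelta(days=d), s) for d, s in fills]
        pdc_all = compute_pdc(fills_df(rows), YEAR_2009)
        assert 0.0 <= pdc_all <= 1.0
        if rows:
            pdc_fewer = compute_pdc(fills_df(rows[:-1]), YEAR_2009)
            assert pdc_all >= pdc_fewer


class TestIndexDmt:
    def test_last_baseline_claim_wins(self):
        claims = pd.concat([fills_df([("2009-03-01", 30)], drug="interferon_beta_1a"),
                            fills_df([("2009-11-15", 30)], drug="glatiramer_acetate")])
        drug, when = identify_index_dmt(claims)
        assert drug == "glatiramer_acetate" and when == pd.Timestamp("2009-11-15")

    def test_same_date_tie_breaks_by_longest_supply(self):
        claims = pd.concat([fills_df([("2009-12-01", 30)], drug="interferon_beta_1b"),
                            fills_df([("2009-12-01", 90)], drug="glatiramer_acetate")])
        assert identify_index_dmt(claims)[0] == "glatiramer_acetate"

    def test_full_tie_breaks_lexicographically(self):
        claims = pd.concat([fills_df([("2009-12-01", 30)], drug="natalizumab"),
                            fills_df([("2009-12-01", 30)], drug="glatiramer_acetate")])
        assert identify_index_dmt(claims)[0] == "glatiramer_acetate"

    def test_requires_a_baseline_claim(self):
        with pytest.raises(ValueError):
            identify_index_dmt(fills_df([]))


class TestDiscontinuation:
    def test_final_runout_with_long_gap_to_censor(self, config):
        ev = detect_discontinuation(fills_df([("2010-03-01", 30)]), config)
        assert ev["kind"] == "discontinuation"
        assert ev["event_date"] == pd.Timestamp("2010-03-31")

    def test_continuous_supply_through_censor_is_censored(self, config):
        rows = [("2009-01-01", 30)]
        d = pd.Timestamp("2009-01-01")
        while d <= pd.Timestamp("2010-12-15"):
            rows.append((d.strftime("%Y-%m-%d"), 30))
            d += pd.Timedelta(days=30)
        assert detect_discontinuation(fills_df(rows), config)["kind"] == "censored"

    def test_gap_truncated_at_censor_below_60_days_is_censored(self, config):
        # run-out 2010-11-20: only 41 days to Dec 31
        ev = detect_discontinuation(fills_df([("2010-10-21", 30)]), config)
        assert ev["kind"] == "censored"

    def test_interior_gap_dated_at_runout(self, config):
        ev = detect_discontinuation(
            fills_df([("2009-02-01", 30), ("2009-06-01", 30)]), config)
        assert ev["kind"] == "discontinuation"
        assert ev["event_date"] == pd.Timestamp("2009-03-03")


class TestSwitchAndInitiation:
    def test_switch_at_first_other_dmt_claim(self, config):
        claims = pd.concat([fills_df([("2009-12-01", 30)], drug="glatiramer_acetate"),
                            fills_df([("2010-05-10", 30)], drug="natalizumab")])
        ev = detect_switch(claims, "glatiramer_acetate", pd.Timestamp("2009-12-01"), config)
        assert ev["kind"] == "switch" and ev["to_drug"] == "natalizumab"
        assert ev["event_date"] == pd.Timestamp("2010-05-10")

    def test_only_index_drug_claims_means_no_switch(self, config):
        claims = fills_df([("2009-12-01", 30), ("2010-02-01", 30)])
        assert detect_switch(claims, "glatiramer_acetate",
                             pd.Timestamp("2009-12-01"), config) is None

    def test_two_new_dmts_record_the_earlier_one(self, config):
        claims = pd.concat([fills_df([("2010-06-01", 30)], drug="natalizumab"),
                            fills_df([("2010-03-01", 30)], drug="interferon_beta_1a")])
        ev = detect_switch(claims, "glatiramer_acetate", pd.Timestamp("2009-12-01"), config)
        assert ev["to_drug"] == "interferon_beta_1a"

    def test_initiation_at_first_followup_claim(self, config):
        ev = detect_initiation(fills_df([("2010-02-01", 30)]), config)
        assert ev["kind"] == "initiation" and ev["event_date"] == pd.Timestamp("2010-02-01")

    def test_initiation_on_censor_date_counts(self, config):
        ev = detect_initiation(fills_df([("2010-12-31", 30)]), config)
        assert ev is not None

    def test_no_claims_means_no_initiation(self, config):
        assert detect_initiation(fills_df([]), config) is None

    def test_baseline_claim_for_naive_patient_is_an_inconsistency(self, config):
        with pytest.raises(ValueError, match="baseline"):
            detect_initiation(fills_df([("2009-06-01", 30)]), config)


class TestClaimExtraction:
    def test_jcode_administrations_get_imputed_supply(self, config):
        med = mk_medical([("P1", "2009-04-01", "2009-04-01", "outpatient", [], "J2323", 3000.0)])
        claims = dmt_claims(mk_pharmacy([]), med, config)
        assert len(claims) == 1
        assert claims.loc[0, "drug"] == "natalizumab"
        assert claims.loc[0, "days_supply"] == config.jcode_days_supply
        assert claims.loc[0, "source"] == "jcode"

    def test_row_order_invariance_of_detection(self, config):
        ph = mk_pharmacy([
            ("P1", "2009-12-01", "glatiramer_acetate", 30, 2000.0),
            ("P1", "2009-01-01", "glatiramer_acetate", 30, 2000.0),
            ("P1", "2010-04-01", "natalizumab", 30, 3000.0),
        ])
        a = dmt_claims(ph, mk_medical([]), config)
        b = dmt_claims(ph.iloc[::-1].reset_index(drop=True), mk_medical([]), config)
        pd.testing.assert_frame_equal(a, b)
        sw_a = detect_switch(a, "glatiramer_acetate", pd.Timestamp("2009-12-01"), config)
        sw_b = detect_switch(b, "glatiramer_acetate", pd.Timestamp("2009-12-01"), config)
        assert sw_a == sw_b
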