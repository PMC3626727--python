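"""Estimation layer: closed-form checks, GLM properties, recycled predictions,
and the bias-corrected paired bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msrelapse.models import (CostModel, RankDeficiencyError, SeparationError,
                              UtilizationModel, Z95, bc_bootstrap, bivariate_table,
                              bootstrap_adjusted_costs, build_design)
from msrelapse.simulate import simulate_analysis_records


def records_from_2x2(a, b, c, d):
    """Exposure-outcome table: a=exposed cases, b=exposed non-cases,
    c=unexposed cases, d=unexposed non-cases."""
    return pd.DataFrame({
        "hra": [1] * (a + b) + [0] * (c + d),
        "y": [1] * a + [0] * b + [1] * c + [0] * d,
    })


# printed 2x2 margins used as closed-form logistic inputs: the first is the
# baseline all-cause ER split by exposure group from the study population
TWO_BY_TWO_CASES = [(386, 631, 4116, 14086), (20, 30, 10, 40), (7, 11, 13, 5)]


class TestLogisticClosedForm:
    @pytest.mark.parametrize("a,b,c,d", TWO_BY_TWO_CASES)
    def test_two_by_two_matches_ln_ad_over_bc(self, a, b, c, d):
        fit = UtilizationModel(records_from_2x2(a, b, c, d), "y", covariates=[]).fit()
        log_or = math.log(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert fit.params["hra"] == pytest.approx(log_or, abs=1e-6)
        assert fit.bse["hra"] == pytest.approx(se, abs=1e-6)

    def test_odds_ratio_exponentiation(self):
        fit = UtilizationModel(records_from_2x2(386, 631, 4116, 14086), "y",
                               covariates=[]).fit()
        tab = fit.odds_ratios().set_index("term")
        beta, se = fit.params["hra"], fit.bse["hra"]
        assert tab.loc["hra", "odds_ratio"] == pytest.approx(math.exp(beta))
        assert tab.loc["hra", "ci_lower"] == pytest.approx(math.exp(beta - Z95 * se))
        assert tab.loc["hra", "ci_upper"] == pytest.approx(math.exp(beta + Z95 * se))
        assert (tab[["ci_lower", "ci_upper"]] > 0).all().all()

    def test_known_wald_interval(self):
        # beta=0.6931 (OR 2), SE=0.1 -> CI (1.644, 2.433)
        lo = math.exp(0.6931 - Z95 * 0.1)
        hi = math.exp(0.6931 + Z95 * 0.1)
        assert (round(lo, 3), round(hi, 3)) == (1.644, 2.433)

    def test_null_covariates_give_or_near_one(self):
        rng = np.random.default_rng(4)
        rec = pd.DataFrame({"hra": rng.integers(0, 2, 4000),
                            "y": rng.integers(0, 2, 4000)})
        tab = UtilizationModel(rec, "y", covariates=[]).fit().odds_ratios()
        assert tab.set_index("term").loc["hra", "odds_ratio"] == pytest.approx(1.0, abs=0.15)

    def test_perfect_separation_raises(self):
        rec = pd.DataFrame({"hra": [0, 0, 0, 1, 1, 1], "y": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(SeparationError):
            UtilizationModel(rec, "y", covariates=[]).fit()

    def test_rank_deficiency_names_the_aliased_term(self):
        rec = records_from_2x2(5, 5, 5, 5)
        rec["hra_copy"] = rec["hra"]
        with pytest.raises(RankDeficiencyError, match="hra_copy"):
            UtilizationModel(rec, "y", covariates=["hra_copy"]).fit()

    def test_categorical_expansion_uses_reference_levels(self):
        rec = records_from_2x2(5, 5, 5, 5)
        rec["region"] = ["northeast", "south"] * 10
        X = build_design(rec, ["hra", "region"])
        assert list(X.columns) == ["const", "hra", "region[south]"]


class TestGammaModel:
    def test_intercept_only_recovers_sample_mean(self):
        rng = np.random.default_rng(8)
        rec = pd.DataFrame({"hra": 0, "cost": rng.gamma(1.5, 9000.0, 500)})
        fit = CostModel(rec, "cost", exposure=None, covariates=[]).fit()
        assert math.exp(fit.params["const"]) == pytest.approx(
            rec["cost"].mean(), rel=1e-6)

    def test_planted_exposure_coefficient_recovered(self):
        rec, truth = simulate_analysis_records(20000, seed=101, cost_ratio=1.8)
        fit = CostModel(rec, "fu_cost_nondmt",
                        covariates=["cci", "any_ms_symptom", "baseline_er",
                                    "baseline_hosp"]).fit()
        se = fit.bse["hra"]
        assert fit.params["hra"] == pytest.approx(math.log(1.8), abs=3 * se)

    def test_equal_costs_edge_handled(self):
        rec = pd.DataFrame({"hra": [0, 1] * 10, "cost": 100.0})
        fit = CostModel(rec, "cost", covariates=[]).fit()
        assert math.exp(fit.params["const"]) == pytest.approx(100.0, rel=1e-6)
        assert fit.dispersion == pytest.approx(0.0, abs=1e-12)

    def test_zero_costs_replaced_by_half_min_positive(self):
        rec = pd.DataFrame({"hra": [0, 1, 0, 1], "cost": [0.0, 50.0, 100.0, 150.0]})
        model = CostModel(rec, "cost", covariates=[])
        assert model.records["cost"].min() == 25.0

    def test_zero_cost_exclusion_policy(self):
        rec = pd.DataFrame({"hra": [0, 1, 0, 1], "cost": [0.0, 50.0, 100.0, 150.0]})
        model = CostModel(rec, "cost", covariates=[], zero_policy="exclude")
        assert len(model.records) == 3


class TestRecycledPredictions:
    def test_zero_exposure_coefficient_gives_zero_difference(self):
        rec = pd.DataFrame({"hra": [0, 1] * 50, "cost": [100.0, 100.0] * 50})
        fit = CostModel(rec, "cost", covariates=[]).fit()
        m1, m0, diff = fit.adjusted_means("hra")
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_single_covariate_closed_form(self):
        # exact fit: saturated single binary covariate model
        rec = pd.DataFrame({"hra": [0] * 4 + [1] * 4,
                            "cost": [100.0] * 4 + [180.0] * 4})
        fit = CostModel(rec, "cost", covariates=[]).fit()
        m1, m0, diff = fit.adjusted_means("hra")
        assert m1 == pytest.approx(180.0, rel=1e-6)
        assert m0 == pytest.approx(100.0, rel=1e-6)
        assert diff == pytest.approx(80.0, rel=1e-6)

    def test_difference_sign_matches_exposure_coefficient(self):
        rec, _ = simulate_analysis_records(3000, seed=5, cost_ratio=0.7)
        fit = CostModel(rec, "fu_cost_nondmt",
                        covariates=["cci", "baseline_hosp"]).fit()
        _, _, diff = fit.adjusted_means("hra")
        assert (diff < 0) == (fit.params["hra"] < 0)


class TestBivariateTable:
    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame({"hra": [0, 1] * 2000, "cci": rng.poisson(0.6, 4000)})
        rec["age"] = 50
        tab = bivariate_table(rec, continuous=("cci",), categorical=())
        assert tab.loc[0, "p_value"] > 0.05

    def test_chi_square_matches_textbook_formula(self):
        # baseline all-cause ER rows of the study's bivariate table
        rec = records_from_2x2(386, 631, 4116, 14086).rename(columns={"y": "baseline_er"})
        tab = bivariate_table(rec, continuous=(), categorical=("baseline_er",))
        observed = np.array([[4116, 14086], [386, 631]], float)
        col = observed.sum(0)
        row = observed.sum(1)
        expected = np.outer(row, col) / observed.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = float(stats.chi2.sf(chi2, 1))
        assert tab["p_value"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_degenerate_variable_flagged_not_fatal(self):
        rec = pd.DataFrame({"hra": [0, 1] * 10, "flat": 1.0, "onecat": "x"})
        tab = bivariate_table(rec, continuous=("flat",), categorical=("onecat",))
        assert tab["p_value"].isna().all()
        assert (tab["note"] == "degenerate").all()


class TestBcBootstrap:
    def test_bit_reproducible_given_seed(self):
        rec, _ = simulate_analysis_records(300, seed=2)
        est = lambda r: float(r["fu_cost_nondmt"].mean())
        r1 = bc_bootstrap(est, rec, B=200, seed=42)
        r2 = bc_bootstrap(est, rec, B=200, seed=42)
        assert (r1.point, r1.se, r1.z0, r1.ci_lower, r1.ci_upper) == \
               (r2.point, r2.se, r2.z0, r2.ci_lower, r2.ci_upper)
        assert np.array_equal(r1.replicates, r2.replicates)

    def test_z0_is_normal_quantile_of_fraction_below(self):
        # engineered replicate set with 30% of replicates below the point
        from msrelapse.models import _bc_interval
        reps = np.concatenate([np.full(30, -1.0), np.full(70, 1.0)])
        z0, _, _ = _bc_interval(reps, 0.0)
        assert z0 == pytest.approx(stats.norm.ppf(0.30))

    def test_symmetric_replicates_collapse_to_percentile_interval(self):
        from msrelapse.models import _bc_interval
        rng = np.random.default_rng(7)
        reps = rng.normal(0.0, 1.0, 4001)
        point = float(np.median(reps))
        z0, lo, hi = _bc_interval(reps, point)
        assert abs(z0) < 0.01
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.05)
        assert hi == pytest.approx(phi, abs=0.05)

    def test_identical_patients_give_zero_width_interval(self):
        rec = pd.DataFrame({"x": [5.0] * 50})
        with pytest.warns(UserWarning, match="degenerate"):
            r = bc_bootstrap(lambda df: float(df["x"].mean()), rec, B=50, seed=0)
        assert r.se == 0.0 and r.ci_lower == r.ci_upper == 5.0

    def test_failing_estimator_aborts_with_diagnostic(self):
        rec = pd.DataFrame({"x": np.arange(20.0)})

        def fails_on_resamples(df):
            # the original sample has no duplicate rows; resamples do
            if df["x"].duplicated().any():
                raise RuntimeError("boom")
            return float(df["x"].mean())

        with pytest.raises(RuntimeError, match="resamples"):
            bc_bootstrap(fails_on_resamples, rec, B=50, seed=0)

    def test_paired_cost_bootstrap_brackets_the_planted_difference(self):
        rec, truth = simulate_analysis_records(1500, seed=77, cost_ratio=1.8)
        out = bootstrap_adjusted_costs(rec, covariates=["cci", "any_ms_symptom",
                                                        "baseline_er", "baseline_hosp"],
                                       B=200, seed=5)
        d = out["difference"]
        assert d.ci_lower < d.point < d.ci_upper
        assert d.ci_lower < truth["marginal_cost_difference"] < d.ci_upper
        # the three components are paired: difference of the arm points
        assert d.point == pytest.approx(out["exposed"].point - out["unexposed"].point)
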