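import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from growthmap import cohort
from growthmap.simulate import SGA_REFERENCE


def _record(**overrides):
    base = dict(suburb_id="s1", birthweight=3300.0, gestation=39, sex="M",
                singleton=True, liveborn=True, primiparous=False,
                maternal_height=164.0, pobw=1.0, sga=False, ses_quintile=3)
    base.update(overrides)
    return base


class TestEligibility:
    def test_gestation_boundary_at_33_weeks(self):
        rec = pd.DataFrame([_record(gestation=32), _record(gestation=33)])
        eligible, counts = cohort.filter_eligible(rec)
        assert len(eligible) == 1
        assert eligible.iloc[0]["gestation"] == 33
        assert counts[cohort.PRETERM] == 1

    def test_stillborn_and_twin_excluded(self):
        rec = pd.DataFrame([_record(liveborn=False), _record(singleton=False),
                            _record()])
        eligible, counts = cohort.filter_eligible(rec)
        assert len(eligible) == 1
        assert counts[cohort.NOT_LIVEBORN] == 1
        assert counts[cohort.NOT_SINGLETON] == 1

    def test_null_pobw_excluded(self):
        rec = pd.DataFrame([_record(pobw=np.nan), _record()])
        _, counts = cohort.filter_eligible(rec)
        assert counts[cohort.NULL_POBW] == 1

    def test_empty_input(self):
        rec = pd.DataFrame(columns=list(_record().keys()))
        eligible, counts = cohort.filter_eligible(rec)
        assert eligible.empty and sum(counts.values()) == 0

    def test_counts_partition_input(self):
        rec = pd.DataFrame([_record(), _record(gestation=30),
                            _record(liveborn=False, gestation=30),
                            _record(pobw=np.nan)])
        _, counts = cohort.filter_eligible(rec)
        assert sum(counts.values()) == len(rec)
        # first failing rule wins: stillborn-and-preterm counts as stillborn
        assert counts[cohort.NOT_LIVEBORN] == 1
        assert counts[cohort.PRETERM] == 1


class TestCaseClassification:
    @pytest.mark.parametrize("pobw,expected", [
        (0.79, True), (0.80, False), (1.00, False)])
    def test_poor_fetal_growth_threshold_is_strict(self, pobw, expected):
        assert cohort.classify_poor_fetal_growth(pobw) is expected

    def test_null_pobw_raises(self):
        with pytest.raises(ValueError):
            cohort.classify_poor_fetal_growth(np.nan)

    def test_sga_strict_below_centile(self):
        cut = SGA_REFERENCE[("M", 39)]
        assert not cohort.classify_sga(cut, "M", 39, SGA_REFERENCE)
        assert cohort.classify_sga(cut - 1, "M", 39, SGA_REFERENCE)

    def test_sga_table_gap_raises(self):
        with pytest.raises(KeyError):
            cohort.classify_sga(2500, "M", 20, SGA_REFERENCE)


class TestAggregation:
    def test_counts_and_ses_attachment(self):
        rec = pd.DataFrame(
            [_record(suburb_id="a", pobw=0.7)]
            + [_record(suburb_id="a") for _ in range(9)]
            + [_record(suburb_id="b") for _ in range(5)])
        ses = pd.Series({"a": 980.0, "b": 1030.0})
        tab = cohort.aggregate_to_suburbs(rec, ses)
        row = tab.set_index("suburb_id").loc["a"]
        assert row["births"] == 10 and row["cases"] == 1
        assert tab["births"].sum() == len(rec)
        assert abs(tab["ses_std"].mean()) < 1e-12

    def test_unknown_suburb_raises(self):
        rec = pd.DataFrame([_record(suburb_id="zz")])
        with pytest.raises(KeyError):
            cohort.aggregate_to_suburbs(rec, pd.Series({"a": 1000.0}))


class TestStandardize:
    def test_closed_form(self):
        out = cohort.standardize_ses([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-1.224745, 0.0, 1.224745], atol=1e-6)

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40),
           st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_invariance(self, xs, a, b):
        xs = np.asarray(xs)
        if np.ptp(xs) < 1e-6:
            return
        np.testing.assert_allclose(cohort.standardize_ses(a * xs + b),
                                   cohort.standardize_ses(xs), atol=1e-6)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            cohort.standardize_ses([2.0, 2.0, 2.0])


class TestOddsRatio:
    def test_symmetry_gives_unity(self):
        assert cohort.odds_ratio_2x2(10, 10, 10, 10)[0] == pytest.approx(1.0)

    def test_closed_form(self):
        assert cohort.odds_ratio_2x2(20, 10, 10, 20)[0] == pytest.approx(4.0)

    def test_hand_computed_example_with_woolf_ci(self):
        oratio, (lo, hi) = cohort.odds_ratio_2x2(13, 87, 10, 130)
        assert oratio == pytest.approx(13 * 130 / (87 * 10), abs=1e-12)
        se = np.sqrt(1 / 13 + 1 / 87 + 1 / 10 + 1 / 130)
        assert lo == pytest.approx(np.exp(np.log(oratio) - 1.96 * se))
        assert hi == pytest.approx(np.exp(np.log(oratio) + 1.96 * se))

    def test_zero_cell_requires_continuity_flag(self):
        with pytest.raises(ValueError):
            cohort.odds_ratio_2x2(0, 10, 10, 10)
        oratio, _ = cohort.odds_ratio_2x2(0, 10, 10, 10,
                                          continuity_correction=True)
        assert oratio == pytest.approx(0.5 * 10.5 / (10.5 * 10.5))


class TestBreslowDay:
    def test_identical_strata_are_perfectly_homogeneous(self):
        chi2, df, p = cohort.breslow_day([(20, 80, 10, 90)] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 4 and p == pytest.approx(1.0)

    def test_five_strata_give_four_df(self):
        tables = [(20 + k, 80, 10, 90) for k in range(5)]
        _, df, _ = cohort.breslow_day(tables)
        assert df == 4

    def test_strong_heterogeneity_detected(self):
        # OR 1 vs OR 9 at n=100 per stratum arm
        chi2, _, p = cohort.breslow_day([(50, 50, 50, 50), (90, 10, 50, 50)])
        assert chi2 > 3.84 and p < 0.05

    def test_degenerate_stratum_raises(self):
        with pytest.raises(ValueError, match="stratum 1"):
            cohort.breslow_day([(10, 10, 10, 10), (0, 0, 5, 5)])

    def test_single_stratum_raises(self):
        with pytest.raises(ValueError):
            cohort.breslow_day([(10, 10, 10, 10)])


class TestChiSquare:
    def test_zero_statistic_gives_unity(self):
        assert cohort.chi_square_upper_tail(0.0, 4) == pytest.approx(1.0)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            cohort.chi_square_upper_tail(1.0, 0)
        with pytest.raises(ValueError):
            cohort.chi_square_upper_tail(-1.0, 2)


class TestPobwNullGof:
    @staticmethod
    def _null_records(fitted, n_per, rng):
        rows = []
        for sid, p in fitted.items():
            sga = rng.random(n_per) < p
            for s in sga:
                rows.append({"suburb_id": sid, "sga": s})
        return pd.DataFrame(rows)

    def test_perfect_fit_gives_zero(self):
        rec = pd.DataFrame([{"suburb_id": "a", "sga": True},
                            {"suburb_id": "a", "sga": False},
                            {"suburb_id": "b", "sga": True},
                            {"suburb_id": "b", "sga": False}])
        fitted = pd.Series({"a": 0.5, "b": 0.5})
        chi2, df, p = cohort.pobw_null_gof(rec, fitted)
        assert chi2 == pytest.approx(0.0)
        assert df == 1

    def test_df_is_contributing_suburbs_minus_one(self):
        rng = np.random.default_rng(0)
        fitted = pd.Series({f"s{k}": 0.1 for k in range(12)})
        rec = self._null_records(fitted, 30, rng)
        _, df, _ = cohort.pobw_null_gof(rec, fitted)
        assert df == 11

    def test_p_uniform_under_the_null(self):
        # records drawn from the fitted probabilities themselves
        from scipy.stats import kstest
        rng = np.random.default_rng(42)
        fitted = pd.Series({f"s{k}": p for k, p in
                            enumerate(rng.uniform(0.05, 0.3, 40))})
        pvals = []
        for _ in range(150):
            rec = self._null_records(fitted, 60, rng)
            pvals.append(cohort.pobw_null_gof(rec, fitted)[2])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_fitted_probability_raises(self):
        rec = pd.DataFrame([{"suburb_id": "zz", "sga": False}])
        with pytest.raises(KeyError):
            cohort.pobw_null_gof(rec, pd.Series({"a": 0.1}))


class TestIncidence:
    def test_percentage_rounding(self):
        assert cohort.incidence_percent(1, 16) == 6.2
        with pytest.raises(ValueError):
            cohort.incidence_percent(1, 0)


class TestSensitivityReport:
    def test_end_to_end_on_synthetic_births(self):
        from conftest import make_suburb_data
        from growthmap.simulate import SimulationParams, simulate_birth_records
        tab, _ = make_suburb_data(6, 6, beta1=-0.25, sigma_v=0.2,
                                  mean_births=250, seed=30)
        params = SimulationParams(pobw_missing_rate=0.15, seed=31)
        rec = simulate_birth_records(tab, params, missing_bias=3.0)
        fitted = pd.Series(tab.set_index("suburb_id")["p_true"])
        rep = cohort.sensitivity_analysis(rec, fitted)
        assert rep.odds_ratio > 1.0
        assert rep.breslow_day_df == 4
        assert 0 <= rep.gof_p <= 1
        text = str(rep)
        assert "Breslow-Day" in text and "odds ratio" in text
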