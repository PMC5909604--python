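"""Risk-factor attribution: regression method, PARF method, joint adjustment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import impactsec as im
from impactsec._util import round_half_away
from impactsec.errors import ConfigurationError, InputValidationError
from impactsec.risk_factors import (
    apply_net_of_treatment,
    compute_risk_factor_dpps,
)
from impactsec.strata import STRATUM_COLS


class TestLogCoefficient:
    def test_cholesterol_worked_example(self):
        assert round_half_away(im.log_coefficient(0.35), 3) == pytest.approx(-0.431)

    @pytest.mark.parametrize("r,beta", [(0.0, 0.0), (0.5, np.log(0.5))])
    def test_closed_forms(self, r, beta):
        assert im.log_coefficient(r) == pytest.approx(beta)

    def test_rejects_reduction_of_one_or_more(self):
        with pytest.raises(InputValidationError):
            im.log_coefficient(1.0)


class TestContinuousDpp:
    def test_cholesterol_worked_example(self):
        dpp = im.continuous_dpp(im.log_coefficient(0.35), 1.28, 176)
        assert round_half_away(dpp, 0) == pytest.approx(75)

    def test_no_change_no_dpps(self):
        assert im.continuous_dpp(-0.4, 0.0, 500) == 0.0

    def test_one_unit_fall_consistency_identity(self):
        # a 1-unit fall averts exactly reduction_per_unit x expected deaths
        for r in (0.1, 0.35, 0.6):
            assert im.continuous_dpp(im.log_coefficient(r), 1.0, 1_000) \
                == pytest.approx(r * 1_000)

    @given(r=st.floats(0.01, 0.8), delta=st.floats(-3.0, 3.0),
           expected=st.floats(0.0, 5_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_repeated_multiplier_oracle(self, r, delta, expected):
        # exp(beta * delta) == (1 - r) ** delta: the per-unit survival
        # multiplier applied delta times
        dpp = im.continuous_dpp(im.log_coefficient(r), delta, expected)
        assert dpp == pytest.approx((1.0 - (1.0 - r) ** delta) * expected)

    def test_worsening_factor_brings_deaths_forward(self):
        assert im.continuous_dpp(im.log_coefficient(0.3), -0.5, 100) < 0


class TestParf:
    def test_diabetes_worked_example_both_years(self):
        assert round_half_away(im.parf(0.043, 1.86), 3) == pytest.approx(0.036)
        assert round_half_away(im.parf(0.082, 1.86), 3) == pytest.approx(0.066)

    @pytest.mark.parametrize("p,rr,value", [(0.0, 5.0, 0.0), (1.0, 2.0, 0.5),
                                            (0.5, 1.0, 0.0)])
    def test_closed_forms(self, p, rr, value):
        assert im.parf(p, rr) == pytest.approx(value)

    def test_protective_exposure_gives_negative_fraction(self):
        assert im.parf(0.3, 0.5) < 0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(InputValidationError):
            im.parf(0.1, 0.0)

    @given(p=st.floats(0.001, 1.0), rr=st.floats(1.001, 20.0),
           dp=st.floats(0.001, 0.5), drr=st.floats(0.001, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_monotonicity(self, p, rr, dp, drr):
        base = im.parf(p, rr)
        assert 0.0 < base < 1.0
        if p + dp <= 1.0:
            assert im.parf(p + dp, rr) > base
        assert im.parf(p, rr + drr) > base


class TestBinaryDpp:
    def test_diabetes_worked_example(self):
        dpp = im.binary_dpp(im.parf(0.043, 1.86), im.parf(0.082, 1.86), 874)
        assert round_half_away(dpp, 0) == pytest.approx(-26)

    def test_equal_parfs_give_zero(self):
        assert im.binary_dpp(0.12, 0.12, 900) == 0.0

    @given(p0=st.floats(0, 1), p1=st.floats(0, 1), rr=st.floats(0.1, 10),
           e=st.floats(0, 2_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_formula_reevaluation_oracle(self, p0, p1, rr, e):
        dpp = im.binary_dpp(im.parf(p0, rr), im.parf(p1, rr), e)
        x0, x1 = p0 * (rr - 1), p1 * (rr - 1)
        assert dpp == pytest.approx(e * (x0 / (1 + x0) - x1 / (1 + x1)))


class TestInterpolateLevels:
    def test_two_point_straight_line_extrapolation(self):
        out = im.interpolate_levels([(1993, 7.0), (2003, 6.0)], (1991, 2007))
        assert out == pytest.approx((7.2, 5.6))

    def test_constant_series(self):
        assert im.interpolate_levels([(1993, 4.0), (2003, 4.0)], (1991, 2007)) \
            == pytest.approx((4.0, 4.0))

    def test_matches_normal_equations_oracle(self):
        pts = [(1993.0, 7.1), (1998.0, 6.4), (2003.0, 6.05)]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        # explicit least-squares normal equations
        xbar, ybar = x.mean(), y.mean()
        slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
        intercept = ybar - slope * xbar
        out = im.interpolate_levels(pts, (1991, 2007))
        assert out[0] == pytest.approx(slope * 1991 + intercept)
        assert out[1] == pytest.approx(slope * 2007 + intercept)

    def test_duplicate_years_rejected(self):
        with pytest.raises(InputValidationError):
            im.interpolate_levels([(1993, 7.0), (1993, 6.0)], (1991, 2007))

    def test_prevalence_clamping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = im.interpolate_levels([(1993, 0.10), (2003, 0.02)], (1991, 2017),
                                        clamp=(0.0, 1.0))
        assert out[1] == 0.0


class TestJointAdjustment:
    def test_single_factor_passes_through(self):
        np.testing.assert_allclose(im.joint_adjustment([37.5], 100.0), [37.5])

    def test_two_equal_factors_closed_form(self):
        adjusted = im.joint_adjustment([20.0, 20.0], 100.0)
        assert adjusted.sum() == pytest.approx(36.0)
        np.testing.assert_allclose(adjusted, [18.0, 18.0])

    @given(fracs=st.lists(st.floats(-0.5, 0.9), min_size=1, max_size=6))
    @settings(max_examples=250, deadline=None)
    def test_total_matches_sequential_survival_oracle(self, fracs):
        expected = 500.0
        gross = [f * expected for f in fracs]
        adjusted = im.joint_adjustment(gross, expected)
        surviving = expected
        for f in fracs:
            surviving *= 1.0 - f
        assert adjusted.sum() == pytest.approx(expected - surviving)
        assert adjusted.sum() < expected

    def test_factor_averting_everything_rejected(self):
        with pytest.raises(InputValidationError):
            im.joint_adjustment([120.0, 10.0], 100.0)

    def test_signs_preserved(self):
        adjusted = im.joint_adjustment([30.0, -10.0, 5.0], 200.0)
        assert (np.sign(adjusted) == [1, -1, 1]).all()


class TestNetOfTreatment:
    def test_simple_subtraction(self):
        assert im.net_of_treatment(100.0, 20.0) == pytest.approx(80.0)
        assert im.net_of_treatment(100.0, 0.0) == pytest.approx(100.0)

    def test_aggregate_net_equals_gross_minus_treatment(self, default_inputs,
                                                        default_result):
        rf = default_result.risk_factor_dpps
        treat = default_result.treatment_dpps
        pairs = default_result.config.net_of_treatment_pairs
        for factor, group in pairs.items():
            gross = rf.loc[rf["factor"] == factor, "dpp"].sum()
            net = rf.loc[rf["factor"] == factor, "net"].sum()
            tdpp = treat.loc[treat["disease_group"] == group, "dpp"].sum()
            assert net == pytest.approx(gross - tdpp)

    def test_missing_pairing_configuration_errors(self, default_inputs):
        from impactsec.strata import expected_deaths

        exp = expected_deaths(default_inputs["mortality"])
        rf = compute_risk_factor_dpps(
            default_inputs["risk_continuous"], default_inputs["risk_binary"], exp)
        with pytest.raises(ConfigurationError, match="pairing"):
            apply_net_of_treatment(rf, None, pairs=None)


class TestComputeRiskFactorDpps:
    def test_worsening_factors_yield_negative_dpps(self, default_result):
        rf = default_result.risk_factor_dpps
        for factor in ("bmi", "diabetes"):
            assert rf.loc[rf["factor"] == factor, "dpp"].sum() < 0

    def test_cumulative_total_below_additive_total(self, default_inputs):
        from impactsec.strata import expected_deaths

        exp = expected_deaths(default_inputs["mortality"])
        args = (default_inputs["risk_continuous"], default_inputs["risk_binary"], exp)
        cumulative = compute_risk_factor_dpps(*args, mode="cumulative")
        additive = compute_risk_factor_dpps(*args, mode="additive")
        assert cumulative["dpp"].sum() < additive["dpp"].sum()

    def test_stratum_totals_never_exceed_expected(self, default_inputs):
        from impactsec.strata import expected_deaths

        exp = expected_deaths(default_inputs["mortality"])
        rf = compute_risk_factor_dpps(
            default_inputs["risk_continuous"], default_inputs["risk_binary"], exp)
        per_stratum = rf.groupby(STRATUM_COLS)[["dpp"]].sum().join(
            exp.set_index(STRATUM_COLS))
        assert (per_stratum["dpp"] < per_stratum["expected"]).all()

    def test_unknown_stratum_in_risk_table_rejected(self, fixture_bundle):
        bundle = {k: v.copy() for k, v in fixture_bundle.items()}
        bundle["risk_binary"].loc[0, "age_band"] = "35-44"
        with pytest.raises(InputValidationError, match="absent"):
            from impactsec.strata import expected_deaths

            compute_risk_factor_dpps(
                bundle["risk_continuous"], bundle["risk_binary"],
                expected_deaths(bundle["mortality"]))
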