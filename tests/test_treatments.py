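"""Treatment net effects, Mant-Hicks polypharmacy adjustment, Table-2 shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import impactsec as im
from impactsec._util import round_half_away
from impactsec.errors import ConfigurationError, InputValidationError
from impactsec.strata import STRATUM_COLS
from impactsec.treatments import compute_treatment_dpps, treatment_table


def _sequential_survival_oracle(treatments):
    """Apply treatments one at a time to a unit cohort; return averted fraction."""
    alive_at_risk = 1.0
    for rrr, uptake in treatments:
        alive_at_risk *= 1.0 - rrr * uptake
    return 1.0 - alive_at_risk


treatment_pairs = st.lists(
    st.tuples(st.floats(0.0, 0.95), st.floats(0.0, 1.0)), min_size=0, max_size=6
)


class TestTreatmentDpp:
    def test_aspirin_worked_example(self):
        dpp = im.treatment_dpp(147, 0.14, 0.97, 1.0, 0.23, 0.34)
        assert round_half_away(dpp, 1) == pytest.approx(9.5)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(uptake_base=0.4, uptake_final=0.4), dict(compliance=0.0)],
        ids=["no-uptake-change", "zero-compliance"],
    )
    def test_zero_cases(self, kwargs):
        args = dict(patients=500, uptake_base=0.1, uptake_final=0.8,
                    compliance=1.0, rrr=0.25, case_fatality=0.3)
        args.update(kwargs)
        assert im.treatment_dpp(**args) == 0.0

    def test_negative_when_uptake_fell(self):
        assert im.treatment_dpp(100, 0.8, 0.2, 1.0, 0.25, 0.3) < 0

    @pytest.mark.parametrize("field,value", [
        ("uptake_base", 1.2), ("uptake_final", -0.1), ("compliance", 2.0),
        ("case_fatality", 1.5), ("rrr", 1.0),
    ])
    def test_out_of_range_proportion_names_field(self, field, value):
        args = dict(patients=10, uptake_base=0.1, uptake_final=0.5,
                    compliance=1.0, rrr=0.2, case_fatality=0.3)
        args[field] = value
        with pytest.raises(InputValidationError, match=field):
            im.treatment_dpp(**args)

    @given(delta=st.floats(min_value=-0.5, max_value=0.5)
           .filter(lambda d: d == 0 or abs(d) > 1e-9))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_uptake_change(self, delta):
        base = im.treatment_dpp(200, 0.5, 0.5, 1.0, 0.25, 0.3)
        moved = im.treatment_dpp(200, 0.5, 0.5 + delta, 1.0, 0.25, 0.3)
        assert base == 0.0
        assert np.sign(moved) == np.sign(delta)

    def test_linear_in_patients(self):
        one = im.treatment_dpp(147, 0.14, 0.97, 1.0, 0.23, 0.34)
        two = im.treatment_dpp(294, 0.14, 0.97, 1.0, 0.23, 0.34)
        assert two == pytest.approx(2 * one)


class TestMantHicks:
    def test_single_treatment_collapse(self):
        assert im.mant_hicks_benefit([(0.23, 1.0)]) == pytest.approx(0.23)

    def test_two_equal_treatments_closed_form(self):
        assert im.mant_hicks_benefit([(0.25, 1.0), (0.25, 1.0)]) == pytest.approx(0.4375)

    def test_empty_list_gives_zero(self):
        assert im.mant_hicks_benefit([]) == 0.0

    @given(treatment_pairs)
    @settings(max_examples=250, deadline=None)
    def test_matches_sequential_survival_oracle(self, pairs):
        assert im.mant_hicks_benefit(pairs) == pytest.approx(
            _sequential_survival_oracle(pairs))

    @given(treatment_pairs)
    @settings(max_examples=250, deadline=None)
    def test_bounded_and_subadditive(self, pairs):
        combined = im.mant_hicks_benefit(pairs)
        individual = [r * u for r, u in pairs]
        assert combined < 1.0
        assert combined <= sum(individual) + 1e-12
        if sum(1 for b in individual if b > 0) <= 1:
            assert combined == pytest.approx(sum(individual))


def _group_rows(treatments, patients=300.0, cf=0.3, stratum=("male", "55-64", 5)):
    sex, age, q = stratum
    return pd.DataFrame(
        [
            {
                "disease_group": "stemi", "treatment": f"t{i}",
                "sex": sex, "age_band": age, "secq": q,
                "patients": patients, "uptake_base": ub, "uptake_final": uf,
                "rrr": rrr, "compliance": c, "case_fatality": cf,
            }
            for i, (rrr, ub, uf, c) in enumerate(treatments)
        ]
    )


class TestGroupDpp:
    def test_modes_coincide_for_single_treatment(self):
        df = _group_rows([(0.23, 0.14, 0.97, 1.0)])
        _, ind = im.group_dpp(df, mode="independent")
        _, mh = im.group_dpp(df, mode="mant_hicks")
        assert ind["dpp"].iloc[0] == pytest.approx(mh["dpp"].iloc[0])

    def test_mant_hicks_subadditive_for_positive_changes(self):
        df = _group_rows([(0.25, 0.1, 0.8, 1.0), (0.3, 0.0, 0.6, 0.9)])
        _, ind = im.group_dpp(df, mode="independent")
        _, mh = im.group_dpp(df, mode="mant_hicks")
        assert mh["dpp"].iloc[0] < ind["dpp"].iloc[0]

    def test_group_total_matches_two_year_oracle(self):
        rng = np.random.default_rng(5)
        specs = [(rng.uniform(0, 0.5), rng.uniform(0, 0.5), rng.uniform(0.5, 1.0),
                  rng.uniform(0.5, 1.0)) for _ in range(5)]
        patients, cf = 412.0, 0.27
        df = _group_rows(specs, patients=patients, cf=cf)
        _, mh = im.group_dpp(df, mode="mant_hicks")
        b_final = _sequential_survival_oracle([(r, uf * c) for r, ub, uf, c in specs])
        b_base = _sequential_survival_oracle([(r, ub * c) for r, ub, uf, c in specs])
        assert mh["dpp"].iloc[0] == pytest.approx(patients * (b_final - b_base) * cf)

    def test_apportionment_preserves_group_total(self):
        df = _group_rows([(0.25, 0.1, 0.8, 1.0), (0.3, 0.7, 0.2, 0.9),
                          (0.15, 0.0, 0.5, 1.0)])
        rows = compute_treatment_dpps(df, mode="mant_hicks")
        surv_b = np.prod(1 - rows["rrr"] * rows["uptake_base"] * rows["compliance"])
        surv_f = np.prod(1 - rows["rrr"] * rows["uptake_final"] * rows["compliance"])
        group_total = 300.0 * (surv_b - surv_f) * 0.3
        assert rows["dpp"].sum() == pytest.approx(group_total)

    def test_unknown_mode_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            compute_treatment_dpps(_group_rows([(0.2, 0.1, 0.5, 1.0)]), mode="bogus")

    def test_mixed_disease_groups_rejected_by_group_dpp(self):
        df = _group_rows([(0.2, 0.1, 0.5, 1.0)])
        df2 = df.copy()
        df2["disease_group"] = "nstemi"
        with pytest.raises(InputValidationError):
            im.group_dpp(pd.concat([df, df2]))

    def test_doubling_patients_doubles_dpps(self, default_inputs):
        t = default_inputs["treatments"]
        base = compute_treatment_dpps(t)
        doubled = compute_treatment_dpps(t.assign(patients=t["patients"] * 2))
        np.testing.assert_allclose(doubled["dpp"], 2 * base["dpp"])


class TestTreatmentTable:
    def test_share_arithmetic_from_printed_totals(self):
        df = _group_rows([(0.2, 0.1, 0.9, 1.0)])
        rows = compute_treatment_dpps(df)
        scale = 2_642.0 / rows["dpp"].sum()
        rows["dpp"] *= scale
        tab = treatment_table(rows, total_dpp=11_111.0)
        assert round_half_away(tab.loc["total_treatment", "pct_of_total"], 1) \
            == pytest.approx(23.8)

    def test_zero_total_dpp_reports_missing_percentages(self):
        rows = compute_treatment_dpps(_group_rows([(0.2, 0.1, 0.9, 1.0)]))
        tab = treatment_table(rows, total_dpp=0.0)
        assert tab["pct_of_total"].isna().all()

    def test_group_shares_sum_to_total_treatment_share(self, default_inputs,
                                                       default_result):
        tab = default_result.treatment_summary
        groups = tab.drop(index="total_treatment")
        assert groups["dpp"].sum() == pytest.approx(tab.loc["total_treatment", "dpp"])
        assert groups["pct_of_total"].sum() == pytest.approx(
            tab.loc["total_treatment", "pct_of_total"])
        for q in range(1, 6):
            assert groups[f"dpp_secq{q}"].sum() == pytest.approx(
                tab.loc["total_treatment", f"dpp_secq{q}"])

    def test_empty_treatments_give_zero_contribution(self):
        empty = pd.DataFrame(columns=["disease_group", "treatment"] + STRATUM_COLS
                             + ["patients", "uptake_base", "uptake_final", "rrr",
                                "compliance", "case_fatality"])
        rows = compute_treatment_dpps(empty)
        tab = treatment_table(rows, total_dpp=500.0)
        assert tab.loc["total_treatment", "dpp"] == 0.0
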