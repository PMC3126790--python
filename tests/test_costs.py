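"""Cost accrual: closed-form component checks, the payer/societal
accounting identity, and base-case ordering."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import modified, uniform_trajectory
from oab_cea.costs import (DIRECT_COMPONENTS, comorbidity_cost, drug_cost,
                           productivity_cost, resource_cost, total_cost)
from oab_cea.engine import run_cohort
from oab_cea.fixtures import random_parameter_set

ARMS = ("fesoterodine", "tolterodine", "solifenacin")


class TestDrugCost:
    def test_full_persistence_full_response_closed_form(self, basecase):
        """One patient-year on tolterodine at 1.70 EUR/day: 364 x 1.70."""
        params = modified(
            basecase,
            persistence__tolterodine__remaining__8=1.0,
            shared_persistence__remaining__12=1.0,
            shared_persistence__remaining__24=1.0,
            shared_persistence__remaining__52=1.0,
        )
        traj = uniform_trajectory("tolterodine", "4mg", 1.0, 0.0)
        assert drug_cost(traj, params) == pytest.approx(364 * 1.70)

    def test_zero_prices_zero_cost(self, basecase):
        params = modified(basecase,
                          unit_costs__drug_per_day__fesoterodine__4mg=0.0,
                          unit_costs__drug_per_day__fesoterodine__8mg=0.0)
        traj = run_cohort("fesoterodine", params)
        assert drug_cost(traj, params) == 0.0

    def test_fesoterodine_base_case_near_hand_oracle(self, basecase):
        # 0.9064 x (28 x 1.70 + 56 x 2.21) + 0.4427 x 84 x 2.21
        #   + 0.3308 x 196 x 2.21  (50/50 mix approximation) ~ 381 EUR
        traj = run_cohort("fesoterodine", basecase)
        assert drug_cost(traj, basecase) == pytest.approx(381, abs=3)


class TestResourceCost:
    def test_fully_incontinent_pads_closed_form(self, basecase):
        traj = uniform_trajectory("tolterodine", "4mg", 0.0, 1.0)
        pads, _ = resource_cost(traj, basecase)
        assert pads == pytest.approx(0.67 * 4.23 * 0.58 * 365, rel=1e-9)

    def test_fully_continent_visits_per_month(self, basecase):
        traj = uniform_trajectory("tolterodine", "4mg", 1.0, 0.0)
        _, visits = resource_cost(traj, basecase)
        monthly = visits / 12
        assert monthly == pytest.approx(
            0.133 * 26.78 + 0.117 * 58.60 + 0.033 * 2.56, abs=1e-9)
        assert monthly == pytest.approx(10.50, abs=0.01)

    def test_zero_utilization_zero_cost(self, basecase):
        params = modified(basecase,
                          **{f"resource_use__{status}__{field}": 0.0
                             for status in ("controlled", "uncontrolled_on_rx",
                                            "untreated")
                             for field in ("frac_using_pads", "pads_per_day",
                                           "gp_visits_per_month",
                                           "specialist_visits_per_month",
                                           "lab_tests_per_month")})
        traj = run_cohort("fesoterodine", params)
        assert resource_cost(traj, params) == (0.0, 0.0)


class TestComorbidityCost:
    def test_fully_uncontrolled_closed_forms(self, basecase):
        traj = uniform_trajectory("tolterodine", "4mg", 0.0, 1.0)
        per_condition = comorbidity_cost(traj, basecase)
        # 0.7 UTIs/person per 6 months, x2 annualized, at 53.1 EUR/episode
        assert per_condition["uti"] == pytest.approx(0.7 * 2 * 53.1, rel=1e-9)
        # 78.3 admissions per 1000 patient-years at 14,831.4 EUR/admitted-year
        assert per_condition["nursing_home"] == pytest.approx(
            78.3 / 1000 * 14831.4, rel=1e-9)
        assert per_condition["fracture"] == pytest.approx(
            0.053 * 2 * 5742.8, rel=1e-9)

    def test_zero_rates_zero_cost(self, basecase):
        params = modified(basecase,
                          **{f"comorbidity__{status}__{field}": 0.0
                             for status in ("controlled", "uncontrolled_on_rx",
                                            "untreated")
                             for field in ("fracture_prob_6mo", "skin_prob_6mo",
                                           "skin_events_per_person",
                                           "uti_prob_6mo", "uti_events_per_person",
                                           "depression_prob_annual",
                                           "nursing_home_admissions_per_1000py")})
        traj = run_cohort("fesoterodine", params)
        assert all(v == 0.0 for v in comorbidity_cost(traj, params).values())


class TestProductivity:
    def test_incontinence_channel_closed_form(self, basecase):
        """One person-year fully continent, uniform 21.1% hours reduction:
        -(0.211 x 40 x 13.51 x 0.5983 x 52) EUR."""
        params = modified(basecase,
                          productivity__hours_reduction_mode="uniform",
                          productivity__nocturia_impairment=0.0)
        traj = uniform_trajectory("tolterodine", "4mg", 1.0, 0.0)
        expected = -(0.211 * 40 * 13.51 * 0.5983 * 52)
        assert productivity_cost(traj, params) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(-3547, abs=1)

    def test_sex_weighted_reduction_is_female_male_mix(self, basecase):
        prod = basecase.productivity
        expected = 0.8087 * 0.08 + (1 - 0.8087) * 0.21
        assert prod.effective_hours_reduction == pytest.approx(expected)

    def test_all_untreated_no_effect(self, basecase):
        traj = uniform_trajectory("tolterodine", "4mg", 0.0, 0.0)
        assert productivity_cost(traj, basecase) == 0.0

    def test_no_employment_no_effect(self, basecase):
        params = modified(basecase, productivity__frac_employed=0.0)
        traj = run_cohort("fesoterodine", params)
        assert productivity_cost(traj, params) == 0.0


class TestTotals:
    def test_accounting_identity_and_signs(self, basecase):
        for arm in ARMS:
            bd = total_cost(run_cohort(arm, basecase), basecase)
            assert bd.total_societal == bd.total_payer + bd.productivity
            assert all(getattr(bd, c) >= 0 for c in DIRECT_COMPONENTS)
            assert bd.productivity <= 0

    def test_perspective_selects_total(self, basecase):
        traj = run_cohort("fesoterodine", basecase)
        societal = total_cost(traj, basecase, "societal")
        payer = total_cost(traj, basecase, "payer")
        assert societal.total == societal.total_societal
        assert payer.total == payer.total_payer
        assert payer.total == societal.total - societal.productivity
        with pytest.raises(ValueError):
            total_cost(traj, basecase, "martian")

    def test_zero_everything_costs_nothing(self, basecase):
        doc = basecase.model_dump()
        uc = doc["unit_costs"]
        for key, value in uc.items():
            if key == "drug_per_day":
                uc[key] = {arm: {d: 0.0 for d in prices}
                           for arm, prices in value.items()}
            else:
                uc[key] = 0.0
        doc["productivity"]["wage_per_hour"] = 0.0
        from oab_cea.parameters import parameter_set_from_internal

        params = parameter_set_from_internal(doc)
        bd = total_cost(run_cohort("fesoterodine", params), params)
        assert bd.total_societal == 0.0

    def test_total_monotone_in_unit_costs(self, basecase):
        base = total_cost(run_cohort("fesoterodine", basecase), basecase).total_payer
        pricier = modified(basecase, unit_costs__pad=2 * 0.58,
                           unit_costs__fracture_event=2 * 5742.8)
        more = total_cost(run_cohort("fesoterodine", pricier), pricier).total_payer
        assert more > base

    def test_base_case_ordering(self, basecase):
        totals = {arm: total_cost(run_cohort(arm, basecase), basecase).total_societal
                  for arm in ARMS}
        assert totals["fesoterodine"] < totals["solifenacin"] < totals["tolterodine"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_accounting_identity_on_random_parameters(self, seed):
        params = random_parameter_set(seed=seed)
        for arm in params.arms:
            bd = total_cost(run_cohort(arm, params), params)
            assert bd.total_societal == bd.total_payer + bd.productivity
            assert all(getattr(bd, c) >= 0 for c in DIRECT_COMPONENTS)
            assert bd.productivity <= 0

    def test_breakdown_export(self, basecase):
        bd = total_cost(run_cohort("fesoterodine", basecase), basecase)
        frame = bd.to_frame()
        assert set(frame.columns) == {"arm", "component", "eur"}
        assert frame.loc[frame.component == "total_societal", "eur"].iloc[0] == \
            pytest.approx(bd.total_societal)
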