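"""Decision-tree cohort propagation: titration split, week-12 gate,
persistence attrition, and conservation/monotonicity properties."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import modified
from oab_cea.engine import (apply_titration, continent_fraction, dose_mix,
                            response_at_w12, run_cohort)
from oab_cea.fixtures import random_parameter_set
from oab_cea.parameters import ConfigurationError, TitrationPolicy

ARMS = ("fesoterodine", "tolterodine", "solifenacin")


class TestTitrationSplit:
    def test_symmetric_split(self):
        split = apply_titration(0.50, TitrationPolicy(
            frac_responders_titrate=0.5, frac_nonresponders_titrate=0.5),
            "4mg", "8mg")
        assert [b.fraction for b in split.branches] == pytest.approx([0.25] * 4)
        assert split.total == pytest.approx(1.0)

    def test_solifenacin_proxy_split(self):
        split = apply_titration(0.5199, TitrationPolicy(
            frac_responders_titrate=0.5, frac_nonresponders_titrate=0.5),
            "5mg", "10mg")
        fracs = [b.fraction for b in split.branches]
        assert fracs == pytest.approx([0.25995, 0.25995, 0.24005, 0.24005])

    def test_single_dose_arm_has_two_branches(self):
        split = apply_titration(0.4947, TitrationPolicy(
            frac_responders_titrate=0.0, frac_nonresponders_titrate=0.0),
            "4mg", None)
        assert split.responder_stay.fraction == pytest.approx(0.4947)
        assert split.nonresponder_stay.fraction == pytest.approx(0.5053)
        assert split.responder_titrate.fraction == 0.0
        assert split.nonresponder_titrate.fraction == 0.0
        assert split.dose_mix() == {"4mg": pytest.approx(1.0)}

    def test_responder_branches_sum_to_response(self):
        split = apply_titration(0.37, TitrationPolicy(
            frac_responders_titrate=0.2, frac_nonresponders_titrate=0.8),
            "a", "b")
        resp = split.responder_stay.fraction + split.responder_titrate.fraction
        assert resp == pytest.approx(0.37)
        assert split.total == pytest.approx(1.0)


class TestWeek12Gate:
    def test_fesoterodine_hand_value(self, basecase):
        arm = basecase.arms["fesoterodine"]
        split = apply_titration(0.50, basecase.titration["fesoterodine"],
                                "4mg", "8mg")
        # 0.25 x (0.8734 + 0.9065 + 0.2105 + 0.2420)
        assert response_at_w12(split, arm) == pytest.approx(0.5581, abs=1e-9)

    def test_tolterodine_hand_value(self, basecase):
        arm = basecase.arms["tolterodine"]
        split = apply_titration(0.4947, basecase.titration["tolterodine"],
                                "4mg", None)
        # 0.4947 x 0.7717 + 0.5053 x 0.1304
        assert response_at_w12(split, arm) == pytest.approx(0.44765111, abs=1e-8)

    def test_missing_conditional_raises(self, basecase):
        arm = basecase.arms["fesoterodine"]
        split = apply_titration(0.5, basecase.titration["fesoterodine"],
                                "4mg", "16mg")
        with pytest.raises(ConfigurationError):
            response_at_w12(split, arm)


class TestCohortTrajectory:
    @pytest.mark.parametrize("arm,w12,w52", [
        ("fesoterodine", 50.6, 33.08),
        ("tolterodine", 40.6, 26.53),
        ("solifenacin", 47.2, 30.85),
    ])
    def test_published_continence(self, basecase, arm, w12, w52):
        traj = run_cohort(arm, basecase)
        assert 100 * continent_fraction(traj, 12) == pytest.approx(w12, abs=0.05)
        assert 100 * continent_fraction(traj, 52) == pytest.approx(w52, abs=0.05)

    def test_week12_split_between_continent_and_on_treatment(self, basecase):
        traj = run_cohort("fesoterodine", basecase)
        occ = traj.at(12)
        # non-responders are still on therapy at the week-12 assessment
        assert occ.on_treatment == pytest.approx(0.9064)
        assert occ.incontinent == pytest.approx(0.9064 - occ.continent)

    def test_conservation_and_monotone_states(self, basecase):
        for arm in ARMS:
            traj = run_cohort(arm, basecase)
            weeks = sorted(traj.checkpoints)
            for week in weeks:
                occ = traj.at(week)
                assert occ.total == pytest.approx(1.0, abs=1e-12)
                assert all(f >= 0 for f in occ.continent_on_rx.values())
                assert all(f >= 0 for f in occ.incontinent_on_rx.values())
                assert occ.untreated >= 0
            for earlier, later in ((12, 24), (24, 52)):
                assert traj.at(later).untreated >= traj.at(earlier).untreated
                assert traj.at(later).continent <= traj.at(earlier).continent

    def test_unknown_arm_and_unknown_week(self, basecase):
        with pytest.raises(ConfigurationError):
            run_cohort("oxybutynin", basecase)
        traj = run_cohort("fesoterodine", basecase)
        with pytest.raises(KeyError):
            traj.at(30)

    def test_export_is_tidy(self, basecase):
        frame = run_cohort("fesoterodine", basecase).to_frame()
        assert list(frame.columns) == ["week", "state", "dose", "fraction"]
        sums = frame.groupby("week")["fraction"].sum()
        assert (sums.round(9) == 1.0).all()


class TestDoseMix:
    def test_fesoterodine_50_50_after_titration(self, basecase):
        traj = run_cohort("fesoterodine", basecase)
        for week in (8, 12):
            mix = dose_mix(traj, week)
            assert mix["4mg"] == pytest.approx(0.5)
            assert mix["8mg"] == pytest.approx(0.5)

    def test_survivor_mix_tilts_to_high_dose(self, basecase):
        # high-dose conditionals are larger, so week-12 survivors skew to 8 mg
        traj = run_cohort("fesoterodine", basecase)
        mix = dose_mix(traj, 52)
        assert mix["8mg"] > 0.5
        assert sum(mix.values()) == pytest.approx(1.0)

    def test_single_dose_arm(self, basecase):
        traj = run_cohort("tolterodine", basecase)
        for week in (8, 12, 24, 52):
            assert dose_mix(traj, week) == {"4mg": pytest.approx(1.0)}

    def test_undefined_when_nobody_on_treatment(self, basecase):
        from conftest import uniform_trajectory

        traj = uniform_trajectory("tolterodine", "4mg", 0.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            dose_mix(traj, 12)


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_occupancy_conservation_on_random_parameters(self, seed):
        params = random_parameter_set(seed=seed)
        for arm in params.arms:
            traj = run_cohort(arm, params)
            for week, occ in traj.checkpoints.items():
                assert occ.total == pytest.approx(1.0, abs=1e-9)
                assert min([occ.untreated, *occ.continent_on_rx.values(),
                            *occ.incontinent_on_rx.values()]) >= -1e-12

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_more_response_never_less_continence(self, seed):
        """Raising the start-dose week-8 response cannot reduce continence."""
        params = random_parameter_set(seed=seed)
        arm = "fesoterodine"
        start = params.arms[arm].start_dose
        base = run_cohort(arm, params)
        r8 = params.arms[arm].doses[start].response_w8
        bumped = modified(
            params, **{f"arms__{arm}__doses__{start}__response_w8":
                       min(r8 + 0.05, 1.0)})
        more = run_cohort(arm, bumped)
        for week in (12, 24, 52):
            assert more.at(week).continent >= base.at(week).continent - 1e-12

    def test_single_dose_arm_invariant_to_titration_policy(self, basecase):
        base = run_cohort("tolterodine", basecase)
        shifted = modified(basecase,
                           titration__tolterodine__frac_responders_titrate=0.9,
                           titration__tolterodine__frac_nonresponders_titrate=0.3)
        assert run_cohort("tolterodine", shifted) == base
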