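"""Scale-up requirements, attrition/replacement dynamics, gaps and costs."""

import math

import pytest
from hypothesis import given, strategies as st

from hrhplan import (
    ProjectionAssumptions,
    StaffingNorms,
    cost_trajectory,
    gap_report,
    national_projection,
    required_staff,
    requirement_path,
    simulate_trajectory,
    usd_millions,
)
from hrhplan.workforce_projection import ProjectionError
from tests.conftest import region_named


class TestRequiredStaff:
    def test_national_requirements_at_target_coverage(self, national, norms):
        """95% of reconstructed national births needs 311 doctors / 1,778 SBAs."""
        doctors = required_staff(national.births, 0.95, norms.deliveries_per_doctor)
        sbas = required_staff(national.births, 0.95, norms.deliveries_per_sba)
        assert math.floor(doctors) == 311
        assert math.floor(sbas) == 1778

    def test_zero_births_needs_nobody(self):
        assert required_staff(0.0, 0.95, 175.0) == 0.0

    def test_invalid_norm_rejected(self):
        with pytest.raises(ProjectionError):
            required_staff(1000.0, 0.5, 0.0)

    @given(
        births=st.floats(min_value=0.0, max_value=1e7),
        coverage=st.floats(min_value=0.0, max_value=1.0),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_linear_in_births_and_coverage(self, births, coverage, scale):
        base = required_staff(births, coverage, 175.0)
        assert required_staff(births * scale, coverage, 175.0) == pytest.approx(
            base * scale, rel=1e-9, abs=1e-9
        )
        if coverage * scale <= 1.0:
            assert required_staff(births, coverage * scale, 175.0) == pytest.approx(
                base * scale, rel=1e-9, abs=1e-9
            )


class TestValidation:
    def test_norms_must_be_ordered(self):
        with pytest.raises(ProjectionError):
            StaffingNorms(deliveries_per_sba=1000.0, deliveries_per_doctor=175.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"attrition": 1.2},
            {"attrition": -0.1},
            {"target_coverage": 0.0},
            {"target_coverage": 1.5},
            {"base_year": 2016},
            {"sba_salary": -1.0},
            {"coverage_path": "exponential"},
        ],
    )
    def test_assumption_invariants(self, kwargs):
        with pytest.raises(ProjectionError):
            ProjectionAssumptions(**kwargs)


class TestTrajectory:
    def test_stock_flow_identity_holds_exactly(self, regions, assumptions, norms):
        from hrhplan import baseline_coverage

        for region in regions:
            path = requirement_path(
                region.births,
                baseline_coverage(region),
                assumptions,
                norms.deliveries_per_doctor,
            )
            traj = simulate_trajectory(
                region.region.doctors, path, assumptions, "doctor"
            )
            prev = None
            for year, stock_t, hires_t in zip(traj.years, traj.stock, traj.hires):
                if prev is None:
                    assert stock_t == pytest.approx(
                        region.region.doctors + hires_t, rel=1e-12
                    )
                else:
                    assert stock_t == pytest.approx(
                        prev * (1 - assumptions.attrition) + hires_t, rel=1e-12
                    )
                prev = stock_t

    def test_ample_stock_and_no_attrition_never_hires(self):
        assumptions = ProjectionAssumptions(attrition=0.0, salary_growth=0.0)
        path = {year: 50.0 for year in assumptions.years}
        traj = simulate_trajectory(100.0, path, assumptions, "doctor")
        assert all(h == 0.0 for h in traj.hires)
        assert all(s == 100.0 for s in traj.stock)
        assert all(c == traj.cost[0] for c in traj.cost)

    def test_national_nurse_stock_decays_untouched(self, national, assumptions, norms):
        """17,032 nurses dwarf the 1,778 requirement: pure 10%/yr decay."""
        traj = national_projection(national, assumptions, norms)["sba"]
        assert traj.cumulative_hires == 0.0
        assert traj.stock[-1] == pytest.approx(17_032 * 0.9**5, rel=1e-12)

    def test_hiring_keeps_stock_at_requirement(self, regions, assumptions, norms):
        from hrhplan import baseline_coverage

        manicaland = region_named(regions, "Manicaland")
        path = requirement_path(
            manicaland.births,
            baseline_coverage(manicaland),
            assumptions,
            norms.deliveries_per_doctor,
        )
        traj = simulate_trajectory(26, path, assumptions, "doctor")
        for req, stock, hires in zip(traj.requirement, traj.stock, traj.hires):
            assert stock >= req - 1e-9
            if hires > 0:
                assert stock == pytest.approx(req, rel=1e-12)

    def test_cumulative_hires_invariant_to_horizon_split(
        self, regions, assumptions, norms
    ):
        """2010-2012 then 2012-2015 accumulates the same hires as 2010-2015."""
        from hrhplan import baseline_coverage

        for region in regions:
            cov = baseline_coverage(region)
            path = requirement_path(
                region.births, cov, assumptions, norms.deliveries_per_doctor
            )
            full = simulate_trajectory(region.region.doctors, path, assumptions, "doctor")

            first = ProjectionAssumptions(base_year=2010, target_year=2012)
            second = ProjectionAssumptions(base_year=2012, target_year=2015)
            traj1 = simulate_trajectory(
                region.region.doctors,
                {y: path[y] for y in first.years},
                first,
                "doctor",
            )
            traj2 = simulate_trajectory(
                traj1.stock[-1], {y: path[y] for y in second.years}, second, "doctor"
            )
            # the splice year appears in both runs; its hires must not double
            assert traj2.hires[0] == 0.0
            combined = traj1.cumulative_hires + traj2.cumulative_hires
            assert combined == pytest.approx(full.cumulative_hires, rel=1e-12, abs=1e-12)

    def test_negative_requirement_rejected(self, assumptions):
        path = {year: -1.0 for year in assumptions.years}
        with pytest.raises(ProjectionError):
            simulate_trajectory(10.0, path, assumptions)


class TestCost:
    def test_base_year_cost_from_current_stocks(self, national, assumptions, norms):
        """17,032 nurses at $2,112 plus 689 doctors at $2,616 => $37.7m."""
        trajectories = national_projection(national, assumptions, norms)
        costs = cost_trajectory(trajectories, assumptions)
        base = costs.loc[costs.year == 2010, "cost_usd"].item()
        assert base == pytest.approx(17_032 * 2112 + 689 * 2616, rel=1e-12)
        assert costs.loc[costs.year == 2010, "cost_usd_millions"].item() == 37.7

    def test_cost_declines_when_attrition_outpaces_salary_growth(
        self, national, assumptions, norms
    ):
        trajectories = national_projection(national, assumptions, norms)
        costs = cost_trajectory(trajectories, assumptions)["cost_usd"]
        assert all(b < a for a, b in zip(costs, costs[1:]))

    def test_final_year_cost(self, national, assumptions, norms):
        trajectories = national_projection(national, assumptions, norms)
        costs = cost_trajectory(trajectories, assumptions)
        assert costs.loc[costs.year == 2015, "cost_usd_millions"].item() == 25.8

    def test_zero_staff_costs_nothing(self, assumptions):
        path = {year: 0.0 for year in assumptions.years}
        trajectories = {
            "sba": simulate_trajectory(0.0, path, assumptions, "sba"),
            "doctor": simulate_trajectory(0.0, path, assumptions, "doctor"),
        }
        costs = cost_trajectory(trajectories, assumptions)
        assert (costs["cost_usd"] == 0.0).all()

    def test_missing_cadre_rejected(self, assumptions):
        path = {year: 0.0 for year in assumptions.years}
        only_sba = {"sba": simulate_trajectory(0.0, path, assumptions, "sba")}
        with pytest.raises(ProjectionError):
            cost_trajectory(only_sba, assumptions)

    def test_millions_are_truncated_not_rounded(self):
        assert usd_millions(37_774_008) == 37.7
        assert usd_millions(25_858_000) == 25.8
        assert usd_millions(0.0) == 0.0


class TestGapReport:
    def test_regional_doctor_gaps(self, regions, assumptions, norms):
        report = gap_report(regions, assumptions, norms, "doctor")
        by_region = dict(zip(report.regions, report.cumulative_additional))
        assert by_region["Manicaland"] == 43
        assert by_region["Bulawayo"] == 0
        assert by_region["Harare"] == 0

    def test_current_need_from_current_deliveries(self, regions, assumptions, norms):
        report = gap_report(regions, assumptions, norms, "doctor")
        need = dict(zip(report.regions, report.current_need))
        assert need["Manicaland"] == 29

    def test_well_staffed_region_has_no_initial_gap(self, regions, assumptions, norms):
        """Matabeleland South's 22 doctors exceed its target requirement, so
        no base-year hires occur there."""
        from hrhplan import baseline_coverage

        mat_south = region_named(regions, "Matabeleland South")
        path = requirement_path(
            mat_south.births,
            baseline_coverage(mat_south),
            assumptions,
            norms.deliveries_per_doctor,
        )
        traj = simulate_trajectory(22, path, assumptions, "doctor")
        assert traj.hires[0] == 0.0
        report = gap_report(regions, assumptions, norms, "doctor")
        need = dict(zip(report.regions, report.need_at_target))
        assert need["Matabeleland South"] < 22

    def test_step_requirement_dominates_linear(self, regions, norms):
        """Front-loading coverage can only increase cumulative hiring."""
        step = ProjectionAssumptions(coverage_path="step")
        linear = ProjectionAssumptions(coverage_path="linear")
        report_step = gap_report(regions, step, norms, "doctor")
        report_linear = gap_report(regions, linear, norms, "doctor")
        for s, l in zip(
            report_step.cumulative_additional, report_linear.cumulative_additional
        ):
            assert s >= l
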