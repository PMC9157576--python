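"""Cohort trace, conservation and discounted cost/QALY accrual."""

import dataclasses

import numpy as np
import pytest

from shpn_cea import (
    ArmSpec,
    CostItem,
    CycleSpec,
    UtilitySchedule,
    WeibullSurvival,
    accrue_costs,
    accrue_qalys,
    evaluate_arm,
    run_trace,
    survival_at,
    transition_probability,
)

DAYS_PER_YEAR = 365.25


def make_arm(
    shape=1.0,
    scale=1e-12,
    costs=(),
    utilities=(1.0, 1.0, 1.0, 1.0, 1.0),
    name="test",
):
    return ArmSpec(
        name=name,
        survival=WeibullSurvival(shape=shape, scale=scale),
        costs=tuple(costs),
        utilities=UtilitySchedule(utilities),
    )


class TestRunTrace:
    def test_no_death_limit_keeps_cohort_alive(self):
        trace = run_trace(make_arm(scale=1e-12), CycleSpec(horizon_cycles=20))
        assert np.allclose(trace.alive, 1.0, atol=1e-10)

    def test_alive_equals_survival_at_cycle_boundaries(self, fixture_config):
        for arm in fixture_config.arms:
            trace = run_trace(arm, fixture_config.cycle)
            u = fixture_config.cycle.u_for(arm.survival)
            expected = survival_at(arm.survival, trace.cycle * u)
            assert np.max(np.abs(trace.alive - expected)) < 1e-12

    def test_conservation_alive_plus_dead_is_one(self, fixture_config):
        trace = run_trace(fixture_config.intervention, fixture_config.cycle)
        assert np.max(np.abs(trace.alive + trace.dead - 1.0)) < 1e-12

    def test_first_cycle_survivors_match_transition_probability(self, fixture_config):
        arm = fixture_config.intervention
        cycle = fixture_config.cycle
        u = cycle.u_for(arm.survival)
        trace = run_trace(arm, cycle)
        assert trace.alive[1] == pytest.approx(
            1.0 - transition_probability(arm.survival, u, u), abs=1e-15
        )


class TestAccrueCosts:
    def test_per_cycle_sum_without_deaths_or_discount(self):
        arm = make_arm(costs=[CostItem("care", 100.0)])
        cycle = CycleSpec(horizon_cycles=10, annual_discount_rate=0.0)
        trace = run_trace(arm, cycle)
        assert accrue_costs(trace, arm, cycle) == pytest.approx(1000.0)

    def test_once_item_accrues_at_model_start_only(self):
        arm = make_arm(costs=[CostItem("setup", 50.0, recurrence="once")])
        for h, r in [(1, 0.0), (43, 0.03)]:
            cycle = CycleSpec(horizon_cycles=h, annual_discount_rate=r)
            trace = run_trace(arm, cycle)
            assert accrue_costs(trace, arm, cycle) == pytest.approx(50.0)

    def test_fixture_intervention_first_cycle_hand_sum(self, fixture_config):
        # once: 64.48 + 359.38 + 8.56 + 365.70 = 798.12
        # per cycle: 421.58 + 221.79 + 41.07 + 675.00 + 111.20 = 1,470.64
        arm = fixture_config.intervention
        cycle = CycleSpec(horizon_cycles=1, annual_discount_rate=0.0)
        trace = run_trace(arm, cycle)
        assert accrue_costs(trace, arm, cycle) == pytest.approx(2268.76)

    def test_applicability_window_limits_accrual(self):
        item = CostItem("PN", 10.0, applies_from_cycle=0, applies_through_cycle=3)
        arm = make_arm(costs=[item])
        cycle = CycleSpec(horizon_cycles=43, annual_discount_rate=0.0)
        trace = run_trace(arm, cycle)
        assert accrue_costs(trace, arm, cycle) == pytest.approx(40.0)

    def test_discounting_strictly_reduces_totals(self, fixture_config):
        arm = fixture_config.intervention
        r0 = dataclasses.replace(fixture_config.cycle, annual_discount_rate=0.0)
        r3 = dataclasses.replace(fixture_config.cycle, annual_discount_rate=0.03)
        _, c0, q0 = evaluate_arm(arm, r0)
        _, c3, q3 = evaluate_arm(arm, r3)
        assert c3 < c0
        assert q3 < q0

    def test_engine_is_linear_in_cost_amounts(self, fixture_config):
        arm = fixture_config.intervention
        doubled = dataclasses.replace(
            arm,
            costs=tuple(
                dataclasses.replace(c, amount=2 * c.amount) for c in arm.costs
            ),
        )
        cycle = fixture_config.cycle
        c1 = accrue_costs(run_trace(arm, cycle), arm, cycle)
        c2 = accrue_costs(run_trace(doubled, cycle), doubled, cycle)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_half_cycle_correction_reduces_recurring_accrual(self, fixture_config):
        arm = fixture_config.intervention
        cycle = fixture_config.cycle
        full = accrue_costs(run_trace(arm, cycle), arm, cycle, half_cycle=False)
        half = accrue_costs(run_trace(arm, cycle), arm, cycle, half_cycle=True)
        assert half < full  # survival is strictly decreasing


class TestAccrueQalys:
    def test_full_health_identity(self):
        arm = make_arm()
        cycle = CycleSpec(horizon_cycles=43, annual_discount_rate=0.0)
        trace = run_trace(arm, cycle)
        assert accrue_qalys(trace, arm, cycle) == pytest.approx(43 * 42 / DAYS_PER_YEAR)

    def test_zero_utility_yields_zero_qalys(self):
        arm = make_arm(utilities=(0.0,) * 5)
        cycle = CycleSpec(horizon_cycles=10)
        trace = run_trace(arm, cycle)
        assert accrue_qalys(trace, arm, cycle) == 0.0

    def test_fixture_single_cycle_uses_visit2_utility(self, fixture_config):
        arm = fixture_config.intervention
        cycle = CycleSpec(horizon_cycles=1, annual_discount_rate=0.0)
        trace = run_trace(arm, cycle)
        assert accrue_qalys(trace, arm, cycle) == pytest.approx(
            0.67 * 42 / DAYS_PER_YEAR, abs=5e-7
        )

    def test_visit_start_mapping_uses_baseline_first(self, fixture_config):
        arm = fixture_config.intervention
        cycle = CycleSpec(horizon_cycles=1, annual_discount_rate=0.0)
        trace = run_trace(arm, cycle)
        got = accrue_qalys(trace, arm, cycle, utility_mapping="visit_start")
        assert got == pytest.approx(0.60 * 42 / DAYS_PER_YEAR)

    def test_constant_utility_matches_restricted_mean_integral(self, fixture_config):
        from scipy.integrate import quad

        surv = fixture_config.intervention.survival
        arm = make_arm(
            shape=surv.shape, scale=surv.scale, utilities=(0.8,) * 5
        )
        cycle = CycleSpec(horizon_cycles=43, annual_discount_rate=0.0)
        trace = run_trace(arm, cycle)
        qaly = accrue_qalys(trace, arm, cycle)
        u = cycle.u_for(arm.survival)
        integral, _ = quad(lambda t: survival_at(surv, t), 0.0, 43 * u, limit=200)
        restricted_mean_years = integral * 42 / DAYS_PER_YEAR
        # the left Riemann sum of a decreasing curve brackets the integral
        cycle_years = 42 / DAYS_PER_YEAR
        overshoot_bound = cycle_years * (1.0 - survival_at(surv, 43 * u))
        assert 0.8 * restricted_mean_years <= qaly
        assert qaly <= 0.8 * (restricted_mean_years + overshoot_bound)


class TestTraceFrame:
    def test_columns_and_cumulative_consistency(self, fixture_config):
        trace, cost, qaly = evaluate_arm(fixture_config.intervention, fixture_config.cycle)
        frame = trace.frame()
        assert list(frame.columns) == [
            "cycle", "alive", "p_death", "cost_inc", "qaly_inc", "cum_cost", "cum_qaly",
        ]
        assert frame["cum_cost"].iloc[-1] == pytest.approx(cost)
        assert frame["cum_qaly"].iloc[-1] == pytest.approx(qaly)
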