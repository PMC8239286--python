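"""State occupancy, discounting and accrual, checked against independent
fine-step integration oracles."""

import dataclasses

import numpy as np
import pytest

import oligocea as oc
from oligocea.curves import curve_value


# ---------------------------------------------------------------------------
# Independent oracle: numerical integration of the continuous-time model on a
# fine grid, built directly from the anchored curves (never through the
# monthly engine).
# ---------------------------------------------------------------------------

def fine_step_totals(arm, costs, utilities, settings, steps_per_month=30):
    H = settings.horizon_months
    n = H * steps_per_month
    t = (np.arange(n) + 0.5) / steps_per_month  # months, midpoints
    os_v = np.array([curve_value(arm.os, x / 12.0) for x in t])
    pfs_v = np.minimum(np.array([curve_value(arm.pfs, x / 12.0) for x in t]), os_v)
    pmd_v = os_v - pfs_v
    disc = (1 + settings.annual_discount_rate) ** (-t / 12.0)
    dt_years = 1.0 / (12.0 * steps_per_month)

    qaly = np.sum((pfs_v * utilities.u_omd + pmd_v * utilities.u_pmd) * disc) * dt_years
    qaly -= arm.ae_onetime_disutility

    scale = (
        arm.systemic_therapy_fraction
        if settings.cost_scaling_mode == "systemic_fraction"
        else 1.0
    )
    state = np.sum(
        (pfs_v * costs.annual_omd_cost + pmd_v * costs.annual_pmd_cost) * disc
    ) * dt_years * scale

    # end-of-life: lump cost on each increment of death probability
    grid = np.arange(n + 1) / steps_per_month
    dead = 1.0 - np.array([curve_value(arm.os, x / 12.0) for x in grid])
    mid_disc = (1 + settings.annual_discount_rate) ** (-t / 12.0)
    eol = np.sum(np.diff(dead) * costs.end_of_life_cost * mid_disc)

    one_time = arm.ae_onetime_cost
    if arm.receives_primary_sabr:
        one_time += costs.sabr_unit_cost
    one_time += (arm.salvage_rt_count / arm.arm_size) * costs.palliative_rt_unit_cost
    one_time += (arm.salvage_sabr_count / arm.arm_size) * costs.sabr_unit_cost

    return state + one_time + eol, qaly


# ---------------------------------------------------------------------------
# compute_trace
# ---------------------------------------------------------------------------

class TestComputeTrace:
    def test_cohort_start(self):
        os_m = oc.MonthlySurvival(np.array([1.0, 1.0]))
        trace = oc.compute_trace(os_m, os_m)
        assert trace.omd[0] == 1.0
        assert trace.pmd[0] == 0.0
        assert trace.dead[0] == 0.0

    def test_partition_subtraction(self):
        os_m = oc.MonthlySurvival(np.array([1.0, 0.88]))
        pfs_m = oc.MonthlySurvival(np.array([1.0, 0.19]))
        trace = oc.compute_trace(os_m, pfs_m)
        assert trace.pmd[1] == pytest.approx(0.69, abs=1e-12)

    def test_extinct_cohort_all_dead(self):
        os_m = oc.MonthlySurvival(np.array([1.0, 0.0]))
        trace = oc.compute_trace(os_m, os_m)
        assert trace.dead[1] == 1.0
        assert trace.omd[1] == trace.pmd[1] == 0.0

    def test_unclipped_pfs_rejected(self):
        os_m = oc.MonthlySurvival(np.array([1.0, 0.5]))
        pfs_m = oc.MonthlySurvival(np.array([1.0, 0.6]))
        with pytest.raises(ValueError, match="dominance"):
            oc.compute_trace(os_m, pfs_m)


# ---------------------------------------------------------------------------
# discounting
# ---------------------------------------------------------------------------

class TestDiscountFactor:
    def test_zero_rate_is_unity(self):
        assert oc.discount_factor(np.arange(0, 200), 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "t_months, expected",
        [(12.0, 1 / 1.03), (24.0, 1.03 ** -2), (0.0, 1.0)],
    )
    def test_annual_compounding(self, t_months, expected):
        assert oc.discount_factor(t_months, 0.03) == pytest.approx(expected, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            oc.discount_factor(-1.0, 0.03)


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------

class TestAccrueQalys:
    def test_full_health_one_year(self):
        months = np.ones(13)
        trace = oc.compute_trace(oc.MonthlySurvival(months), oc.MonthlySurvival(months))
        utilities = oc.Utilities(u_omd=1.0, u_pmd=1.0)
        settings = oc.EconSettings(annual_discount_rate=0.0, horizon_months=12)
        assert oc.accrue_qalys(trace, utilities, 0.0, settings) == pytest.approx(1.0)

    def test_two_cycle_toy_mid_cycle_rule(self):
        # boundaries: month0 omd=1; month1 omd=1; month2 omd=0.5, pmd=0.5
        os_m = oc.MonthlySurvival(np.array([1.0, 1.0, 1.0]))
        pfs_m = oc.MonthlySurvival(np.array([1.0, 1.0, 0.5]))
        trace = oc.compute_trace(os_m, pfs_m)
        utilities = oc.Utilities(u_omd=0.8, u_pmd=0.6)
        settings = oc.EconSettings(annual_discount_rate=0.0, horizon_months=2)
        # month 1: occupancy (1, 0) -> 0.8; month 2: mid-cycle (0.75, 0.25)
        # -> 0.75*0.8 + 0.25*0.6 = 0.75; each month contributes value/12
        expected = (0.8 + 0.75) / 12.0
        assert oc.accrue_qalys(trace, utilities, 0.0, settings) == pytest.approx(
            expected, abs=1e-12
        )

    def test_disutility_subtracted_once(self):
        months = np.ones(13)
        trace = oc.compute_trace(oc.MonthlySurvival(months), oc.MonthlySurvival(months))
        settings = oc.EconSettings(annual_discount_rate=0.0, horizon_months=12)
        with_d = oc.accrue_qalys(trace, oc.Utilities(1.0, 1.0), 0.002, settings)
        assert with_d == pytest.approx(1.0 - 0.002)


class TestAccrueCosts:
    def test_all_zero_costs(self, ref_inputs):
        arm = dataclasses.replace(
            ref_inputs.arm("SC"), ae_onetime_cost=0.0, salvage_rt_count=0
        )
        costs = oc.StateCosts(0.0, 0.0, 0.0, 0.0, 0.0)
        res = oc.run_arm(arm, costs, ref_inputs.utilities, ref_inputs.settings)
        assert res.total_cost == 0.0

    def test_sc_salvage_component_arithmetic(self, ref_inputs, base_results):
        # (23 / 33) * 11,070 expected salvage plus the 997 adverse-event item
        one_time = base_results["SC"].cost_breakdown["one_time"]
        assert one_time - 997.0 == pytest.approx(23 / 33 * 11_070, abs=1e-6)

    def test_breakdown_sums_to_total(self, base_results):
        for res in base_results.values():
            assert sum(res.cost_breakdown.values()) == pytest.approx(
                res.total_cost, abs=1e-6
            )

    def test_end_of_life_bounded_by_lump_sum(self, ref_inputs, base_results):
        c_eol = ref_inputs.costs.end_of_life_cost
        for name, res in base_results.items():
            deaths = res.trace.dead[-1]
            assert res.cost_breakdown["end_of_life"] <= c_eol * deaths + 1e-9
            # undiscounted bound: exactly c_eol * cumulative deaths at rate 0
        undisc = dataclasses.replace(
            ref_inputs.settings, annual_discount_rate=0.0
        )
        for arm in ref_inputs.arms:
            res = oc.run_arm(arm, ref_inputs.costs, ref_inputs.utilities, undisc)
            assert res.cost_breakdown["end_of_life"] == pytest.approx(
                c_eol * res.trace.dead[-1], abs=1e-6
            )


class TestRunArm:
    def test_immortal_free_cohort(self):
        curve = oc.SurvivalCurve(((0.0, 1.0), (1.0, 1.0)))
        arm = oc.ArmSpec(
            name="X", os=curve, pfs=curve, arm_size=10,
            systemic_therapy_fraction=1.0, ae_onetime_cost=0.0,
            ae_onetime_disutility=0.0, salvage_rt_count=0,
            salvage_sabr_count=0, receives_primary_sabr=False,
        )
        res = oc.run_arm(
            arm, oc.StateCosts(0, 0, 0, 0, 0), oc.Utilities(1.0, 1.0),
            oc.EconSettings(annual_discount_rate=0.0, horizon_months=12),
        )
        assert res.total_cost == 0.0
        assert res.total_qaly == pytest.approx(1.0)

    def test_deterministic_repeatability(self, ref_inputs):
        a = oc.run_model(ref_inputs)
        b = oc.run_model(ref_inputs)
        for name in a:
            assert a[name].total_cost == b[name].total_cost
            assert a[name].total_qaly == b[name].total_qaly

    def test_zero_discount_equals_plain_sums(self, undiscounted_inputs):
        for arm in undiscounted_inputs.arms:
            res = oc.run_arm(
                arm, undiscounted_inputs.costs, undiscounted_inputs.utilities,
                undiscounted_inputs.settings,
            )
            trace = res.trace
            mid_omd = 0.5 * (trace.omd[:-1] + trace.omd[1:])
            mid_pmd = 0.5 * (trace.pmd[:-1] + trace.pmd[1:])
            plain_qaly = (
                np.sum(mid_omd * 0.82 + mid_pmd * 0.59) / 12.0
                - arm.ae_onetime_disutility
            )
            assert res.total_qaly == pytest.approx(plain_qaly, abs=1e-9)
            plain_state = (
                np.sum(mid_omd * 97_440 + mid_pmd * 189_840)
                * arm.systemic_therapy_fraction / 12.0
            )
            assert res.cost_breakdown["state"] == pytest.approx(plain_state, abs=1e-9)

    def test_monthly_engine_tracks_daily_oracle(self, ref_inputs):
        for arm in ref_inputs.arms:
            res = oc.run_arm(
                arm, ref_inputs.costs, ref_inputs.utilities, ref_inputs.settings
            )
            oracle_cost, oracle_qaly = fine_step_totals(
                arm, ref_inputs.costs, ref_inputs.utilities, ref_inputs.settings
            )
            assert res.total_cost == pytest.approx(oracle_cost, rel=0.01)
            assert res.total_qaly == pytest.approx(oracle_qaly, rel=0.01)

    def test_oracle_step_refinement_converges(self, ref_inputs):
        # halving the oracle step changes totals by < 0.5%: the continuous
        # integral is well-resolved, so the 1% engine check is meaningful
        arm = ref_inputs.arm("SABR")
        c30, q30 = fine_step_totals(
            arm, ref_inputs.costs, ref_inputs.utilities, ref_inputs.settings, 30
        )
        c60, q60 = fine_step_totals(
            arm, ref_inputs.costs, ref_inputs.utilities, ref_inputs.settings, 60
        )
        assert abs(c60 - c30) / c30 < 0.005
        assert abs(q60 - q30) / q30 < 0.005
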