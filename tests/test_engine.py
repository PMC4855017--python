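import numpy as np
import pytest

from amdcea.calibration import build_schedule
from amdcea.engine import (
    annual_drug_cost,
    annual_followup_cost,
    annual_treatment_cost,
    cycle_costs,
    cycle_qalys,
    discount_factor,
    run_cohort,
    strategy_result,
    vision_years,
)
from amdcea.parameters import ParameterError
from amdcea.states import ALL_STRATEGIES, Lesion, Strategy

from conftest import make_params


class TestDiscounting:
    def test_time_zero(self):
        assert discount_factor(0.0, 0.03) == 1.0

    def test_one_year(self):
        assert discount_factor(1.0, 0.03) == pytest.approx(0.970874, abs=5e-7)

    def test_ten_years(self):
        assert discount_factor(10.0, 0.03) == pytest.approx(0.744094, abs=5e-7)

    def test_zero_rate_is_exact_identity(self):
        assert discount_factor(7.25, 0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            discount_factor(-1.0, 0.03)


class TestCycleCosts:
    def test_ranibizumab_year1_drug_and_injection(self, params):
        # 8 injections x (1523.8 drug + 41.3 procedure) = 12,520.8 annually,
        # of which the drug itself is 12,190.4
        assert annual_treatment_cost(params, Strategy.RANIBIZUMAB, 1) == \
            pytest.approx(8 * (1523.8 + 41.3))
        assert annual_drug_cost(params, Strategy.RANIBIZUMAB, 1) == \
            pytest.approx(12190.4)
        full_alive = np.array([1.0, 0, 0, 0, 0, 0])
        per_cycle = cycle_costs(params, Strategy.RANIBIZUMAB, full_alive, 1)
        assert per_cycle >= 8 * (1523.8 + 41.3) / 4

    def test_bevacizumab_year2_drug_component(self, params):
        assert annual_drug_cost(params, Strategy.BEVACIZUMAB, 2) == pytest.approx(63.0)

    def test_treatment_stops_after_two_years(self, params):
        for strategy in ALL_STRATEGIES:
            assert annual_treatment_cost(params, strategy, 3) == 0.0

    def test_usual_care_has_no_active_treatment(self, params):
        assert annual_treatment_cost(params, Strategy.USUAL_CARE, 1) == 0.0

    def test_dead_cohort_costs_nothing(self, params):
        dead = np.array([0, 0, 0, 0, 0, 1.0])
        for strategy in ALL_STRATEGIES:
            assert cycle_costs(params, strategy, dead, 1) == 0.0

    def test_comorbidity_costs_only_low_vision_states(self, params):
        best = np.array([1.0, 0, 0, 0, 0, 0])
        worst = np.array([0, 0, 0, 0, 1.0, 0])
        base = annual_followup_cost(params) / 4
        assert cycle_costs(params, Strategy.USUAL_CARE, best, 3) == pytest.approx(base)
        comorb = params.costs.comorbidity_annual_cost() / 4
        assert cycle_costs(params, Strategy.USUAL_CARE, worst, 3) == \
            pytest.approx(base + comorb)

    def test_sae_only_in_active_years_of_injection_arms(self, params):
        alive = np.array([1.0, 0, 0, 0, 0, 0])
        in_y1 = cycle_costs(params, Strategy.BEVACIZUMAB, alive, 1)
        in_y3 = cycle_costs(params, Strategy.BEVACIZUMAB, alive, 3)
        sae = params.costs.sae_annual_cost(Strategy.BEVACIZUMAB) / 4
        treat = annual_treatment_cost(params, Strategy.BEVACIZUMAB, 1) / 4
        assert in_y1 - in_y3 == pytest.approx(treat + sae)
        # PDT has no SAE inputs
        assert params.costs.sae_annual_cost(Strategy.PDT) == 0.0


class TestCycleQalys:
    def test_best_state_quarter(self, params):
        occ = np.array([1.0, 0, 0, 0, 0, 0])
        assert cycle_qalys(params.utilities, occ, 0.25) == pytest.approx(0.2225)

    def test_dead_contributes_nothing(self, params):
        occ = np.array([0, 0, 0, 0, 0, 1.0])
        assert cycle_qalys(params.utilities, occ, 0.25) == 0.0

    def test_uniform_occupancy(self, params):
        occ = np.array([0.2] * 5 + [0.0])
        expected = 0.25 * np.mean([0.89, 0.81, 0.57, 0.52, 0.40])
        assert cycle_qalys(params.utilities, occ, 0.25) == pytest.approx(expected)
        assert expected == pytest.approx(0.1595)


class TestRunCohort:
    def test_one_year_undiscounted_full_health(self):
        p = make_params(zero_mortality=True, zero_transitions=True,
                        utilities=1.0, discount_rate=0.0)
        sched = build_schedule(p, Strategy.USUAL_CARE, Lesion.OCCULT)
        trace = run_cohort(p, sched, max_cycles=4)
        assert trace.total_qalys == pytest.approx(1.0, abs=1e-12)

    def test_one_year_discounted_annuity(self):
        # 0.25 x (1 + 1.03^-0.25 + 1.03^-0.5 + 1.03^-0.75) = 0.98901
        p = make_params(zero_mortality=True, zero_transitions=True,
                        utilities=1.0, discount_rate=0.03)
        sched = build_schedule(p, Strategy.USUAL_CARE, Lesion.OCCULT)
        trace = run_cohort(p, sched, max_cycles=4)
        assert trace.total_qalys == pytest.approx(0.98901, abs=5e-6)

    def test_survival_curve_matches_hand_computed_product(self, params):
        p = make_params(zero_transitions=True)
        sched = build_schedule(p, Strategy.USUAL_CARE, Lesion.OCCULT)
        trace = run_cohort(p, sched)
        # alive fraction after k cycles = prod of per-cycle survival factors
        surv = np.cumprod([1.0 - m[0, 5] for m in sched.matrices])
        alive = 1.0 - trace.occupancy[1:, 5]
        n = len(alive)
        np.testing.assert_allclose(alive, surv[:n], atol=1e-12)

    def test_occupancy_conserved_and_death_monotone(self, params):
        for strategy in ALL_STRATEGIES:
            sched = build_schedule(params, strategy, Lesion.PREDOMINANTLY_CLASSIC)
            trace = run_cohort(params, sched)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(np.diff(trace.occupancy[:, 5]) >= -1e-15)

    def test_discounted_totals_never_exceed_undiscounted(self, params):
        sched = build_schedule(params, Strategy.BEVACIZUMAB, Lesion.OCCULT)
        trace = run_cohort(params, sched)
        assert trace.total_cost <= trace.total_cost_undiscounted
        assert trace.total_qalys <= trace.total_qalys_undiscounted

    def test_zero_rate_discounting_is_identity(self):
        p = make_params(discount_rate=0.0)
        sched = build_schedule(p, Strategy.USUAL_CARE, Lesion.OCCULT)
        trace = run_cohort(p, sched)
        assert trace.total_cost == trace.total_cost_undiscounted
        assert trace.total_qalys == trace.total_qalys_undiscounted

    def test_zero_costs_give_zero_total(self):
        p = make_params(zero_costs=True)
        for strategy in ALL_STRATEGIES:
            res = strategy_result(p, strategy, Lesion.OCCULT)
            assert res.cost == 0.0

    def test_person_time_bounded_by_horizon(self, params):
        sched = build_schedule(params, Strategy.USUAL_CARE, Lesion.OCCULT)
        trace = run_cohort(params, sched)
        n = len(trace.ages)
        person_years = trace.occupancy[:n, :5].sum() * 0.25
        horizon = params.life_table.terminal_age + 1 - params.cohort.start_age
        assert 0 < person_years <= horizon

    def test_mismatched_start_age_rejected(self, params):
        sched = build_schedule(params, Strategy.USUAL_CARE, Lesion.OCCULT)
        params.cohort.start_age = 60.0
        with pytest.raises(ParameterError, match="different starting age"):
            run_cohort(params, sched)

    def test_trace_frame_columns(self, params):
        sched = build_schedule(params, Strategy.USUAL_CARE, Lesion.OCCULT)
        df = run_cohort(params, sched).to_frame()
        assert {"cycle", "age", "cost_cycle", "qaly_cycle", "cum_disc_cost",
                "cum_disc_qaly"}.issubset(df.columns)


class TestVisionYears:
    def test_two_years_in_best_state(self):
        p = make_params(zero_mortality=True, zero_transitions=True,
                        initial_distribution=[1.0, 0, 0, 0, 0])
        sched = build_schedule(p, Strategy.USUAL_CARE, Lesion.OCCULT)
        trace = run_cohort(p, sched, max_cycles=8)
        assert vision_years(trace, p) == pytest.approx(2.0)

    def test_blind_cohort_has_zero_vision_years(self):
        p = make_params(zero_transitions=True,
                        initial_distribution=[0, 0, 0, 0, 1.0])
        sched = build_schedule(p, Strategy.USUAL_CARE, Lesion.OCCULT)
        assert vision_years(run_cohort(p, sched), p) == 0.0

    def test_half_cohort_seeing_for_one_year(self):
        p = make_params(zero_mortality=True, zero_transitions=True,
                        initial_distribution=[0.5, 0, 0, 0, 0.5])
        sched = build_schedule(p, Strategy.USUAL_CARE, Lesion.OCCULT)
        trace = run_cohort(p, sched, max_cycles=4)
        assert vision_years(trace, p) == pytest.approx(0.5)


def test_raising_any_utility_never_decreases_qalys(params):
    from amdcea.sensitivity import set_parameter
    from amdcea.parameters import UTILITY_KEYS
    base = strategy_result(params, Strategy.USUAL_CARE, Lesion.OCCULT).qalys
    for key, vr in zip(UTILITY_KEYS, params.utilities.values):
        bumped = set_parameter(params, f"utilities.{key}", min(1.0, vr.base + 0.05))
        q = strategy_result(bumped, Strategy.USUAL_CARE, Lesion.OCCULT).qalys
        assert q >= base


def test_half_cycle_correction_switch_changes_accrual(params):
    sched = build_schedule(params, Strategy.USUAL_CARE, Lesion.OCCULT)
    plain = run_cohort(params, sched)
    params.cohort.half_cycle_correction = True
    corrected = run_cohort(params, sched)
    assert corrected.total_qalys < plain.total_qalys  # occupancy only decays
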