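import numpy as np
import pytest

from amdcea.economics import icer
from amdcea.engine import strategy_result
from amdcea.parameters import ParameterError
from amdcea.sensitivity import (
    PSAResult,
    compute_ceac,
    default_tornado_spec,
    one_way,
    run_psa,
    sample_psa_parameters,
    scenario_initial_state,
    set_parameter,
    tornado,
    tornado_frame,
)
from amdcea.states import ALL_STRATEGIES, Lesion, Strategy

LES = Lesion.OCCULT


class TestSetParameter:
    def test_utility_pin(self, params):
        p = set_parameter(params, "utilities.va_20_400_or_worse", 0.29)
        assert p.utilities.utility(4) == 0.29
        assert params.utilities.utility(4) == 0.40  # original untouched

    def test_cost_pin(self, params):
        p = set_parameter(params, "costs.unit.bevacizumab_dose", 13.1)
        assert p.costs.unit["bevacizumab_dose"].base == 13.1

    def test_risk_ratio_pin_is_year_specific(self, params):
        pid = "risk_ratios.bevacizumab_vs_ranibizumab.occult.year1.gain"
        p = set_parameter(params, pid, 1.104)
        assert p.risk_ratios["bevacizumab_vs_ranibizumab"][LES][1].rr_gain == 1.104
        assert p.risk_ratios["bevacizumab_vs_ranibizumab"][LES][2].rr_gain == 0.92

    def test_trial_outcome_pin(self, params):
        pid = "trial_outcomes.usual_care.occult.year1.loss_gt6"
        p = set_parameter(params, pid, 0.25)
        assert p.trial_outcomes[(Strategy.USUAL_CARE, LES, 1)].p_loss_gt6 == 0.25

    def test_bound_violations_rejected_before_running(self, params):
        with pytest.raises(ParameterError, match=r"out of \[0,1\]"):
            set_parameter(params, "utilities.va_better_20_40", 1.4)
        with pytest.raises(ParameterError):
            set_parameter(params, "costs.unit.oct", -5.0)
        with pytest.raises(ParameterError, match="cannot resolve|unknown"):
            set_parameter(params, "nonsense.path", 1.0)


class TestOneWay:
    def test_degenerate_range_equals_base_case(self, params):
        base = params.costs.unit["bevacizumab_dose"].base
        r = one_way(params, "costs.unit.bevacizumab_dose", base, base, LES)
        assert r.icer_low == pytest.approx(r.icer_base, rel=1e-12)
        assert r.icer_high == pytest.approx(r.icer_base, rel=1e-12)

    def test_icer_monotone_in_drug_price(self, params):
        r = one_way(params, "costs.unit.bevacizumab_dose", 7.9, 13.1, LES)
        assert r.icer_low < r.icer_base < r.icer_high

    def test_short_horizon_inflates_icer(self, params):
        r = one_way(params, "horizon_years", 2.0, 10.0, LES)
        assert r.icer_low > r.icer_high > r.icer_base

    def test_reversed_bounds_rejected(self, params):
        with pytest.raises(ParameterError, match="low bound exceeds"):
            one_way(params, "costs.unit.oct", 10.0, 5.0, LES)

    def test_empty_tornado_spec_gives_empty_report(self, params):
        assert tornado(params, LES, spec=[]) == []
        assert tornado_frame([]).empty

    def test_default_tornado_spec_covers_reported_parameters(self, params):
        ids = [pid for pid, _, _ in default_tornado_spec(params, LES)]
        assert "cohort.start_age" in ids
        assert "horizon_years" in ids
        assert any("bevacizumab_vs_ranibizumab" in p for p in ids)
        assert sum("utilities." in p for p in ids) == 5


class TestScenario:
    def test_unchanged_scenario_reproduces_base_case(self, params):
        icers = scenario_initial_state(params, LES)
        uc = strategy_result(params, Strategy.USUAL_CARE, LES)
        bev = strategy_result(params, Strategy.BEVACIZUMAB, LES)
        assert icers[Strategy.BEVACIZUMAB] == pytest.approx(icer(uc, bev).value)

    def test_younger_cohorts_get_better_value(self, params):
        at55 = scenario_initial_state(params, LES, state=1, age=55.0)
        at88 = scenario_initial_state(params, LES, state=1, age=88.0)
        assert at55[Strategy.BEVACIZUMAB] < at88[Strategy.BEVACIZUMAB]

    def test_worst_initial_state_erodes_treatment_value(self, params):
        base = scenario_initial_state(params, LES)[Strategy.BEVACIZUMAB]
        blind = scenario_initial_state(params, LES, state=4)[Strategy.BEVACIZUMAB]
        assert blind >= base

    def test_invalid_state_rejected(self, params):
        with pytest.raises(ParameterError):
            scenario_initial_state(params, LES, state=5)


class TestPSASampling:
    def test_fixed_seed_reproducible(self, params):
        a = sample_psa_parameters(params, 5, seed=42)
        b = sample_psa_parameters(params, 5, seed=42)
        for pa, pb in zip(a, b):
            assert pa.trial_outcomes == pb.trial_outcomes
            assert pa.costs.unit == pb.costs.unit
            assert [v.base for v in pa.utilities.values] == \
                [v.base for v in pb.utilities.values]

    def test_lognormal_cost_moments(self, params):
        draws = sample_psa_parameters(params, 10_000, seed=3)
        base = params.costs.unit["ranibizumab_dose"].base
        sampled = np.array([p.costs.unit["ranibizumab_dose"].base for p in draws])
        assert sampled.mean() == pytest.approx(base, rel=0.02)
        assert sampled.std() == pytest.approx(0.2 * base, rel=0.05)
        assert np.all(sampled > 0)

    def test_beta_utility_moments_and_support(self, params):
        draws = sample_psa_parameters(params, 10_000, seed=4)
        sampled = np.array([p.utilities.utility(0) for p in draws])
        assert np.all((sampled >= 0) & (sampled <= 1))
        assert sampled.mean() == pytest.approx(0.89, rel=0.02)

    def test_outcome_triples_stay_feasible(self, params):
        for p in sample_psa_parameters(params, 200, seed=5):
            for probs in p.trial_outcomes.values():
                assert sum(probs.as_tuple()) <= 1.0

    def test_bevacizumab_rr_draw_shared_across_years(self, params):
        for p in sample_psa_parameters(params, 10, seed=6):
            by_lesion = p.risk_ratios["bevacizumab_vs_ranibizumab"]
            assert by_lesion[LES][1] == by_lesion[LES][2]

    def test_degenerate_distributions_return_base(self, params):
        (p,) = sample_psa_parameters(params, 1, seed=0, sd_fraction=0.0)
        assert p.trial_outcomes == params.trial_outcomes
        assert p.costs.unit == params.costs.unit
        assert [v.base for v in p.utilities.values] == \
            [v.base for v in params.utilities.values]


class TestRunPSA:
    def test_degenerate_psa_equals_base_case_exactly(self, params):
        psa = run_psa(params, LES, n=1, seed=9, sd_fraction=0.0)
        for j, s in enumerate(psa.strategies):
            base = strategy_result(params, s, LES)
            assert psa.costs[0, j] == base.cost
            assert psa.qalys[0, j] == base.qalys

    def test_fixed_seed_bit_identical(self, params):
        a = run_psa(params, LES, n=5, seed=31)
        b = run_psa(params, LES, n=5, seed=31)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_ranibizumab_gains_qalys_in_most_draws(self, params):
        psa = run_psa(params, LES, n=40, seed=13)
        d_qaly = psa.qalys[:, psa.column(Strategy.RANIBIZUMAB)] - \
            psa.qalys[:, psa.column(Strategy.USUAL_CARE)]
        assert np.mean(d_qaly > 0) > 0.9

    def test_ce_plane_shape(self, params):
        psa = run_psa(params, LES, n=8, seed=2)
        df = psa.ce_plane()
        assert set(df["strategy"]) == {"pdt", "ranibizumab", "bevacizumab"}
        assert len(df) == 8 * 3


class TestCEAC:
    def _toy_psa(self, costs, qalys):
        costs, qalys = np.asarray(costs, float), np.asarray(qalys, float)
        return PSAResult(lesion=LES, strategies=ALL_STRATEGIES,
                         costs=costs, qalys=qalys, seed=0)

    def test_probabilities_sum_to_one(self, params):
        psa = run_psa(params, LES, n=20, seed=8)
        curve = compute_ceac(psa, np.arange(0.0, 30001.0, 1000.0))
        np.testing.assert_allclose(curve.probability.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_wtp_picks_cheapest(self):
        rng = np.random.default_rng(0)
        costs = rng.uniform(1e3, 1e4, size=(50, 4))
        qalys = rng.uniform(1, 5, size=(50, 4))
        curve = compute_ceac(self._toy_psa(costs, qalys), np.array([0.0]))
        freq = np.bincount(np.argmin(costs, axis=1), minlength=4) / 50
        np.testing.assert_allclose(curve.probability[0], freq)

    def test_huge_wtp_picks_max_qalys(self):
        rng = np.random.default_rng(1)
        costs = rng.uniform(1e3, 1e4, size=(50, 4))
        qalys = rng.uniform(1, 5, size=(50, 4))
        curve = compute_ceac(self._toy_psa(costs, qalys), np.array([1e9]))
        freq = np.bincount(np.argmax(qalys, axis=1), minlength=4) / 50
        np.testing.assert_allclose(curve.probability[0], freq)

    def test_degenerate_single_winner_probability_one(self):
        costs = np.tile([100.0, 200.0, 300.0, 400.0], (10, 1))
        qalys = np.tile([4.0, 3.0, 2.0, 1.0], (10, 1))
        curve = compute_ceac(self._toy_psa(costs, qalys),
                             np.array([0.0, 1e4, 1e8]))
        np.testing.assert_allclose(curve.probability[:, 0], 1.0)

    def test_pairwise_variant_reference_column(self, params):
        psa = run_psa(params, LES, n=20, seed=14)
        curve = compute_ceac(psa, np.array([7480.0]),
                             pairwise_reference=Strategy.USUAL_CARE)
        j = psa.column(Strategy.BEVACIZUMAB)
        expected = psa.prob_cost_effective_pairwise(Strategy.BEVACIZUMAB, 7480.0)
        assert curve.probability[0, j] == pytest.approx(expected)

    def test_empty_grid_rejected(self, params):
        psa = run_psa(params, LES, n=2, seed=1)
        with pytest.raises(ParameterError, match="empty"):
            compute_ceac(psa, np.array([]))

    def test_to_frame_cardinality(self, params):
        psa = run_psa(params, LES, n=5, seed=4)
        grid = np.arange(0.0, 30001.0, 250.0)
        df = compute_ceac(psa, grid).to_frame()
        assert len(df) == len(grid) * 4
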