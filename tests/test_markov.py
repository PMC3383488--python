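"""Markov cohort engine: matrix structure, propagation, accruals."""

import dataclasses

import numpy as np
import pytest

from ptsd_cea import (build_transition_matrix, evaluate_all,
                      evaluate_strategy, run_cohort)
from ptsd_cea import markov as mk
from ptsd_cea.markov import (DEATH_OTHER, DEATH_SUICIDE, DEP, DEP_SSRI,
                             N_STATES, PTSD, PTSD_DEP, PTSD_DEP_SSRI, TUN1,
                             WELL, SimplexError, cycle_matrices,
                             discount_factors)
from ptsd_cea.synthetic import ScenarioSpec, generate_scenario
from ptsd_cea.tree import EndStateDistribution, StrategyDefinition


def _zero_hazard_params(params):
    """All transitions off: no recurrence, remission, recovery or death."""
    updates = {"p_dep_recurrence": 0.0, "p_dep_spont_remission": 0.0,
               "p_ssri_depression": 0.0}
    for pid, p in params.parameters().items():
        if pid.startswith(("suicide_", "other_cause_", "ptsd_recovery_")):
            updates[pid] = 0.0
    return params.with_values(updates)


class TestTransitionMatrix:
    def test_first_cycle_recovery_rate_and_no_adolescent_suicide(self, params):
        M = build_transition_matrix(0, params)
        # year 2 recovery band; age 11 (band 10-14, suicide structurally 0)
        assert M[PTSD, WELL] == pytest.approx(0.0083, rel=1e-4)
        alive = [s for s in range(N_STATES) if s != DEATH_SUICIDE]
        assert np.all(M[alive, DEATH_SUICIDE] == 0.0)

    def test_age_20_suicide_hazard_for_comorbid_state(self, params):
        M = build_transition_matrix(36, params)  # age 20 -> 20-29 band
        assert M[PTSD_DEP, DEATH_SUICIDE] == pytest.approx(0.000343)
        assert M[PTSD_DEP_SSRI, DEATH_SUICIDE] == pytest.approx(0.000343)

    @pytest.mark.parametrize("cycle", [0, 36, 77, 119])
    def test_forbidden_cells_are_structural_zeros(self, params, cycle):
        M = build_transition_matrix(cycle, params)
        assert M[PTSD_DEP, DEP] == 0.0
        assert M[WELL, PTSD] == 0.0
        assert M[WELL, PTSD_DEP] == 0.0

    def test_death_rows_are_identity(self, params):
        M = build_transition_matrix(50, params)
        for s in (DEATH_SUICIDE, DEATH_OTHER):
            row = np.zeros(N_STATES)
            row[s] = 1.0
            assert np.array_equal(M[s], row)

    @pytest.mark.parametrize("treated", [0.0, 1.0])
    def test_rows_sum_to_one_every_cycle(self, params, treated):
        mats = cycle_matrices(params, treated)
        assert np.allclose(mats.sum(axis=2), 1.0, atol=1e-12)
        assert mats.min() >= 0.0

    def test_untreated_depression_routes_off_ssri(self, params):
        M = build_transition_matrix(0, params, treated_fraction=0.0)
        assert M[WELL, DEP] > 0.0
        assert M[WELL, DEP_SSRI] == 0.0

    def test_cycle_outside_horizon_rejected(self, params):
        with pytest.raises(IndexError):
            build_transition_matrix(120, params)
        with pytest.raises(IndexError):
            build_transition_matrix(-1, params)


class TestRunCohort:
    def test_dead_cohort_accrues_nothing(self, params, strategy_map):
        init = np.zeros(N_STATES)
        init[DEATH_OTHER] = 1.0
        trace = run_cohort(init, params, strategy_map["tfcbt"])
        assert trace.total_qalys == 0.0
        assert trace.total_cost == 0.0

    def test_well_cohort_bounds(self, params, strategy_map):
        init = np.zeros(N_STATES)
        init[WELL] = 1.0
        trace = run_cohort(init, params, strategy_map["no_treatment"])
        assert trace.total_qalys < 0.87 * 30
        assert trace.total_qalys > 0.85 * 30 * 1.05 ** -31

    def test_invalid_simplex_rejected(self, params, strategy_map):
        with pytest.raises(SimplexError):
            run_cohort(np.full(N_STATES, 0.5), params, strategy_map["tfcbt"])

    def test_midpoint_discount_factors(self, params):
        d = discount_factors(params)
        # cycle 35 midpoint sits 1 + 35.5/4 = 9.875 years after baseline
        assert d[35] == pytest.approx(1.05 ** -9.875, abs=1e-12)
        assert 1.05 ** -10 == pytest.approx(0.61391, abs=5e-6)

    def test_zero_hazard_limit_matches_closed_form(self, params,
                                                   strategy_map):
        frozen = _zero_hazard_params(params)
        init = np.zeros(N_STATES)
        init[WELL] = 1.0
        trace = run_cohort(init, frozen, strategy_map["no_treatment"])
        d = discount_factors(frozen)
        u = np.array([0.87 if 11 + c / 4 < 30 else 0.85 for c in range(120)])
        assert trace.total_qalys == pytest.approx(float((0.25 * u * d).sum()),
                                                  abs=1e-9)
        assert trace.total_cost == 0.0

    def test_mass_conservation_across_scenarios(self, params):
        scenarios = [params] + [
            generate_scenario(ScenarioSpec(seed=s), template=params)
            for s in (11, 12)]
        from ptsd_cea.tree import default_strategies
        for scen in scenarios:
            for strat in default_strategies(scen):
                from ptsd_cea.tree import arm_endstate_distribution
                trace = run_cohort(arm_endstate_distribution(strat, scen),
                                   scen, strat)
                assert np.allclose(trace.occupancy.sum(axis=1), 1.0,
                                   atol=1e-12)
                dead = trace.occupancy[:, [DEATH_SUICIDE, DEATH_OTHER]].sum(1)
                assert np.all(np.diff(dead) >= -1e-15)

    def test_no_inflow_to_ptsd_states_from_well(self, params, strategy_map):
        init = np.zeros(N_STATES)
        init[WELL] = 1.0
        trace = run_cohort(init, params, strategy_map["tfcbt"])
        assert np.all(trace.occupancy[:, [PTSD, PTSD_DEP, PTSD_DEP_SSRI]] == 0.0)


class TestEvaluateStrategy:
    def test_base_case_qaly_ordering(self, params, strategies):
        res = {r.strategy: r for r in evaluate_all(params, strategies)}
        assert (res["no_treatment"].qaly < res["counselling"].qaly
                < res["tfcbt"].qaly < res["tfcbt_ssri"].qaly)

    def test_identical_arms_give_identical_results(self, params):
        arms = [StrategyDefinition(name, p_response=0.4)
                for name in ("counselling", "tfcbt", "tfcbt_ssri")]
        res = [evaluate_strategy(a, params) for a in arms]
        assert len({(round(r.cost, 10), round(r.qaly, 10)) for r in res}) == 1

    def test_qalys_increase_with_response_probability(self, params):
        qalys = [evaluate_strategy(
            StrategyDefinition("tfcbt", p_response=p), params).qaly
            for p in (0.1, 0.42, 0.8)]
        assert qalys[0] < qalys[1] < qalys[2]

    def test_qalys_strictly_decrease_when_suicide_rises(self, params,
                                                        strategy_map):
        base = evaluate_strategy(strategy_map["tfcbt"], params).qaly
        worse = params.with_values({"suicide_ptsd_dep_20_29": 0.003})
        assert evaluate_strategy(strategy_map["tfcbt"], worse).qaly < base

    def test_undiscounted_totals_dominate_discounted(self, params,
                                                     strategies):
        import copy
        free = copy.deepcopy(params)
        free.settings.discount_rate_annual = 0.0
        for s in strategies:
            r0 = evaluate_strategy(s, free)
            r5 = evaluate_strategy(s, params)
            assert r0.qaly >= r5.qaly
            assert r0.cost >= r5.cost

    def test_no_treatment_accrues_zero_cost_over_full_horizon(
            self, params, strategy_map):
        assert evaluate_strategy(strategy_map["no_treatment"], params).cost == 0.0
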