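"""Synthetic scenarios and the microsimulation validation oracle.

``generate_scenario`` draws random but structurally valid parameter sets
(probabilities, costs, utilities, hazards within realistic bounds) for
property-based testing of the engines.  ``microsimulate`` replays the
identical decision-tree and Markov transition structure person-by-person,
sampling each individual's year-1 branch and 120 categorical per-cycle
transitions from the same matrices the cohort engine uses, and accruing
the same half-cycle-corrected discounted utilities and costs.  Its sample
mean is an unbiased Monte-Carlo estimate of the cohort engine's
expectation, so agreement within sampling error validates the cohort
arithmetic end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import markov as mk
from .markov import (cycle_matrices, cost_vector, discount_factors,
                     utility_vector, evaluate_strategy, N_STATES,
                     _SUICIDE_GROUP, _age_at_cycle)
from .params import ParameterSet, SUICIDE_GROUPS, load_parameters
from .tree import (StrategyDefinition, arm_first_year_cost, default_strategies,
                   baseline_mix_utility)


@dataclass(frozen=True)
class ScenarioSpec:
    """Bounds for random scenario generation (uniform unless noted)."""

    seed: int
    prob_bounds: tuple[float, float] = (0.05, 0.95)
    cost_bounds: tuple[float, float] = (5.0, 500.0)  # log-uniform
    utility_bounds: tuple[float, float] = (0.3, 0.95)
    suicide_max: float = 0.002  # per-cycle
    other_cause_max: float = 0.001
    schedule_bounds: tuple[float, float] = (0.0005, 0.02)


_PROB_IDS = ("p_response_tfcbt", "p_response_tfcbt_ssri",
             "p_response_counselling", "p_ssri_depression",
             "p_comorbid_depression", "p_delayed_response",
             "p_spont_remit_year1", "p_dep_spont_remission",
             "p_dep_recurrence")
_COST_IDS = ("sertraline_month", "psychologist_first",
             "psychologist_subsequent", "psychiatrist_first",
             "psychiatrist_subsequent", "gp_consult", "parent_component")


def generate_scenario(spec: ScenarioSpec,
                      template: ParameterSet | None = None) -> ParameterSet:
    """Random valid ParameterSet; deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    base = template if template is not None else load_parameters()
    lo, hi = spec.prob_bounds
    updates: dict[str, float] = {pid: rng.uniform(lo, hi) for pid in _PROB_IDS}

    clo, chi = np.log(spec.cost_bounds)
    updates.update({pid: float(np.exp(rng.uniform(clo, chi)))
                    for pid in _COST_IDS})

    ulo, uhi = spec.utility_bounds
    disease = {pid: rng.uniform(ulo, uhi)
               for pid in ("u_ptsd", "u_ptsd_dep", "u_dep")}
    updates.update(disease)
    floor = max(disease.values())
    updates["u_well_10_30"] = rng.uniform(floor, max(uhi, floor))
    updates["u_well_30_40"] = rng.uniform(floor, updates["u_well_10_30"])

    for band in base.mortality.age_bands[1:]:
        b = f"{band[0]}_{band[1]}"
        p_ptsd = rng.uniform(0.0, spec.suicide_max / 2)
        updates[f"suicide_general_{b}"] = rng.uniform(0.0, spec.suicide_max / 20)
        updates[f"suicide_ptsd_only_{b}"] = p_ptsd
        updates[f"suicide_ptsd_dep_{b}"] = rng.uniform(p_ptsd, spec.suicide_max)
        updates[f"suicide_dep_only_{b}"] = rng.uniform(0.0, spec.suicide_max / 2)
    for band in base.mortality.age_bands:
        updates[f"other_cause_{band[0]}_{band[1]}"] = \
            rng.uniform(0.0, spec.other_cause_max)

    slo, shi = spec.schedule_bounds
    for ylo, yhi, _ in base.pathways.ptsd_recovery_schedule:
        pid = (f"ptsd_recovery_y{ylo}" if ylo == yhi
               else f"ptsd_recovery_y{ylo}_{yhi}")
        updates[pid] = rng.uniform(slo, shi)

    scenario = base.with_values(updates)
    violations = scenario.validate()
    if violations:  # construction should guarantee validity
        raise AssertionError(f"generated scenario invalid: {violations}")
    return scenario


@dataclass
class MicroEstimate:
    """Sample means and standard errors from an individual-level replay."""

    strategy: str
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n: int
    # aggregate audit trails
    transition_counts: np.ndarray = field(repr=False, default=None)
    suicide_events: np.ndarray = field(repr=False, default=None)  # band x group
    suicide_exposure: np.ndarray = field(repr=False, default=None)


def microsimulate(params: ParameterSet, strategy: StrategyDefinition,
                  n: int, seed: int) -> MicroEstimate:
    """Simulate ``n`` individuals through the tree and all Markov cycles.

    Individuals carry a years-since-baseline clock identical to the cohort
    engine's cycle index; the two computations share one transition-matrix
    builder and differ only in expectation versus sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eff, pw, ut, st = (params.effectiveness, params.pathways,
                       params.utilities, params.settings)

    # ---- year-1 branches
    if strategy.name == "no_treatment":
        p_resp, p_half = 0.0, eff.p_spont_remit_year1
    else:
        p_resp = strategy.p_response
        p_half = (1.0 - p_resp) * eff.p_delayed
    u = rng.random(n)
    branch = np.full(n, 2, dtype=np.int8)  # 0 resp, 1 delayed/spont, 2 none
    branch[u < p_resp + p_half] = 1
    branch[u < p_resp] = 0
    has_dep = rng.random(n) < pw.p_comorbid_depression

    u_well = ut.u_well_10_30
    u_base = np.where(has_dep, ut.u_ptsd_dep, ut.u_ptsd)
    well_frac = np.choose(branch, [0.75, 0.5, 0.0])
    qaly = well_frac * u_well + (1.0 - well_frac) * u_base
    if st.discount_year1:
        qaly /= (1.0 + st.discount_rate_annual) ** 0.5
    cost = np.full(n, arm_first_year_cost(strategy, params))

    # ---- Markov phase
    state = np.empty(n, dtype=np.int64)
    state[branch < 2] = mk.WELL
    dep_state = mk.PTSD_DEP_SSRI if strategy.second_line_ssri else mk.PTSD_DEP
    state[(branch == 2) & has_dep] = dep_state
    state[(branch == 2) & ~has_dep] = mk.PTSD

    treated = 1.0 if strategy.second_line_ssri else 0.0
    matrices = cycle_matrices(params, treated)
    cum = matrices.cumsum(axis=2)
    n_cycles = st.n_cycles
    disc = discount_factors(params)
    cvec = cost_vector(params)
    cycle_frac = st.cycle_length_months / 12.0
    U = np.stack([utility_vector(c, params) for c in range(n_cycles)])

    group_idx = {g: i for i, g in enumerate(SUICIDE_GROUPS)}
    n_bands = len(params.mortality.age_bands)
    trans_counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    sui_events = np.zeros((n_bands, len(SUICIDE_GROUPS)), dtype=np.int64)
    sui_exposure = np.zeros_like(sui_events)

    new = np.empty_like(state)
    for c in range(n_cycles):
        band = params.mortality.band_index(_age_at_cycle(c, params))
        r = rng.random(n)
        for s in np.unique(state):
            mask = state == s
            dest = np.searchsorted(cum[c, s], r[mask], side="right")
            new[mask] = dest
            trans_counts[s] += np.bincount(dest, minlength=N_STATES)
            if s < mk.DEATH_SUICIDE:
                g = group_idx[_SUICIDE_GROUP[s]]
                sui_exposure[band, g] += int(mask.sum())
                sui_events[band, g] += int((dest == mk.DEATH_SUICIDE).sum())
        qaly += cycle_frac * 0.5 * (U[c][state] + U[c][new]) * disc[c]
        cost += 0.5 * (cvec[state] + cvec[new]) * disc[c]
        state, new = new.copy(), state

    se = (lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
    return MicroEstimate(
        strategy=strategy.name,
        mean_cost=float(cost.mean()), mean_qaly=float(qaly.mean()),
        se_cost=se(cost), se_qaly=se(qaly), n=n,
        transition_counts=trans_counts,
        suicide_events=sui_events, suicide_exposure=sui_exposure,
    )


def oracle_report(n_scenarios: int, n_individuals: int, seed: int,
                  include_default: bool = True) -> pd.DataFrame:
    """Cohort engine vs microsimulation across random scenarios.

    One row per (scenario, strategy) with the cohort expectation, the
    microsimulated mean, standard errors and z-scores; ``passed`` flags
    agreement within 3 standard errors on both cost and QALYs.
    """
    base = load_parameters()
    rows = []
    scenario_seeds = np.random.SeedSequence(seed).generate_state(n_scenarios + 1)
    for i in range(n_scenarios):
        if include_default and i == 0:
            scen, label = base, "default"
        else:
            scen = generate_scenario(
                ScenarioSpec(seed=int(scenario_seeds[i]) % (2 ** 31)),
                template=base)
            label = f"scenario_{i}"
        for j, strat in enumerate(default_strategies(scen)):
            cohort = evaluate_strategy(strat, scen)
            micro = microsimulate(scen, strat, n_individuals,
                                  seed=int(scenario_seeds[-1]) % (2 ** 31) + i * 7 + j)
            z_q = ((micro.mean_qaly - cohort.qaly) / micro.se_qaly
                   if micro.se_qaly > 0 else 0.0)
            z_c = ((micro.mean_cost - cohort.cost) / micro.se_cost
                   if micro.se_cost > 0 else
                   (0.0 if abs(micro.mean_cost - cohort.cost) < 1e-9 else np.inf))
            rows.append({
                "scenario": label, "strategy": strat.name,
                "cohort_qaly": cohort.qaly, "micro_qaly": micro.mean_qaly,
                "se_qaly": micro.se_qaly, "z_qaly": z_q,
                "cohort_cost": cohort.cost, "micro_cost": micro.mean_cost,
                "se_cost": micro.se_cost, "z_cost": z_c,
                "passed": bool(abs(z_q) <= 3.0 and abs(z_c) <= 3.0),
            })
    return pd.DataFrame(rows)
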