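"""First-year decision tree.

For each management strategy the first 12 months partition the cohort into
responders, delayed responders and non-responders.  Responders carry the
mixed disease utility for the first 3 months of the year and the well
utility for the remaining 9; delayed responders (and, in the untreated
arm, spontaneous remitters) for 6 of 12 months; non-responders stay at the
mixed disease utility all year.  The end-of-year state shares seed the
long-term Markov model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import ParameterSet

STRATEGY_NAMES = ("no_treatment", "counselling", "tfcbt", "tfcbt_ssri")


@dataclass(frozen=True)
class StrategyDefinition:
    """One treatment arm and its costing recipe."""

    name: str
    p_response: float
    n_sessions: int = 12
    includes_parent_component: bool = True
    includes_ssri: bool = False
    ssri_months_in_arm: int = 3  # trial drug exposure was 12 weeks
    gp_monitoring_visits: int = 2
    # access to second-line SSRI for depression in the Markov phase; the
    # untreated arm never contacts the care system and accrues no cost
    second_line_ssri: bool = True


def default_strategies(params: ParameterSet) -> list[StrategyDefinition]:
    """The four modelled arms at the current effectiveness values."""
    eff = params.effectiveness
    return [
        StrategyDefinition("no_treatment", p_response=0.0, n_sessions=0,
                           includes_parent_component=False,
                           second_line_ssri=False),
        StrategyDefinition("counselling", eff.p_response["counselling"]),
        StrategyDefinition("tfcbt", eff.p_response["tfcbt"]),
        StrategyDefinition("tfcbt_ssri", eff.p_response["tfcbt_ssri"],
                           includes_ssri=True),
    ]


@dataclass
class EndStateDistribution:
    """Cohort shares over health states at the end of the first year."""

    share_well: float
    share_ptsd_only: float
    share_ptsd_dep: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.share_well, self.share_ptsd_only, self.share_ptsd_dep)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())


@dataclass
class TreeResult:
    strategy: str
    cost_year1: float
    qaly_year1: float
    end_states: EndStateDistribution


def baseline_mix_utility(p_dep: float, utilities) -> float:
    """Average utility of the symptomatic cohort at baseline.

    A share ``p_dep`` carries co-morbid depression (PTSD+depression
    utility); the rest carry the PTSD-only utility.
    """
    if not 0.0 <= p_dep <= 1.0:
        raise ValueError(f"p_dep {p_dep} outside [0, 1]")
    return p_dep * utilities.u_ptsd_dep + (1.0 - p_dep) * utilities.u_ptsd


def arm_endstate_distribution(strategy: StrategyDefinition,
                              params: ParameterSet) -> EndStateDistribution:
    """End-of-year-1 cohort shares for one arm.

    Treated arms: responders plus delayed responders (a share of the
    apparent non-responders) reach the well state.  The untreated arm
    reaches it only through spontaneous remission.  The residual keeps its
    baseline depression split.
    """
    p_dep = params.pathways.p_comorbid_depression
    if strategy.name == "no_treatment":
        well = params.effectiveness.p_spont_remit_year1
    else:
        p = strategy.p_response
        well = p + (1.0 - p) * params.effectiveness.p_delayed
    residual = 1.0 - well
    return EndStateDistribution(
        share_well=well,
        share_ptsd_only=residual * (1.0 - p_dep),
        share_ptsd_dep=residual * p_dep,
    )


def arm_first_year_qalys(strategy: StrategyDefinition,
                         params: ParameterSet) -> float:
    """Expected QALYs accrued during the first year.

    Benefit fractions: responders 9/12 of the year well, delayed
    responders and untreated spontaneous remitters 6/12, non-responders
    0/12.  No discounting is applied within year 1 unless the
    ``discount_year1`` setting is on (costs are up-front and benefits
    accrue within the year).
    """
    ut = params.utilities
    u_mix = baseline_mix_utility(params.pathways.p_comorbid_depression, ut)
    u_well = ut.u_well_10_30
    if strategy.name == "no_treatment":
        p_resp, p_half = 0.0, params.effectiveness.p_spont_remit_year1
    else:
        p_resp = strategy.p_response
        p_half = (1.0 - p_resp) * params.effectiveness.p_delayed
    p_none = 1.0 - p_resp - p_half
    q = (p_resp * (0.25 * u_mix + 0.75 * u_well)
         + p_half * (0.5 * u_mix + 0.5 * u_well)
         + p_none * u_mix)
    if params.settings.discount_year1:
        q /= (1.0 + params.settings.discount_rate_annual) ** 0.5
    return q


def arm_first_year_cost(strategy: StrategyDefinition,
                        params: ParameterSet) -> float:
    """Treatment cost of the first year for one arm.

    Half the cohort is treated by psychologists and half by psychiatrists
    (first plus subsequent consultations); one parental component per
    child where flagged; the combination arm adds the trial-duration
    sertraline course and GP monitoring visits.
    """
    if strategy.n_sessions == 0:
        return 0.0
    co = params.costs
    n_sub = strategy.n_sessions - 1
    therapy = 0.5 * (co.psychologist_first + n_sub * co.psychologist_subsequent) \
        + 0.5 * (co.psychiatrist_first + n_sub * co.psychiatrist_subsequent)
    cost = therapy
    if strategy.includes_parent_component:
        cost += co.parent_component
    if strategy.includes_ssri:
        cost += (strategy.ssri_months_in_arm * co.sertraline_month
                 + strategy.gp_monitoring_visits * co.gp_consult)
    return cost


def evaluate_tree(strategy: StrategyDefinition,
                  params: ParameterSet) -> TreeResult:
    return TreeResult(
        strategy=strategy.name,
        cost_year1=arm_first_year_cost(strategy, params),
        qaly_year1=arm_first_year_qalys(strategy, params),
        end_states=arm_endstate_distribution(strategy, params),
    )


def tree_results_frame(params: ParameterSet,
                       strategies=None) -> pd.DataFrame:
    """Per-arm first-year results as a tidy table (CSV-ready)."""
    strategies = strategies or default_strategies(params)
    rows = []
    for s in strategies:
        r = evaluate_tree(s, params)
        rows.append({
            "strategy": r.strategy,
            "cost_year1": r.cost_year1,
            "qaly_year1": r.qaly_year1,
            "share_well": r.end_states.share_well,
            "share_ptsd_only": r.end_states.share_ptsd_only,
            "share_ptsd_dep": r.end_states.share_ptsd_dep,
        })
    return pd.DataFrame(rows)
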