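"""Long-term Markov cohort engine.

The cohort leaving the 12-month decision tree is propagated through a
3-month-cycle state-transition model for 30 years (120 cycles, ages 11 to
41).  Nine logical health states are realised as 11 matrix columns: well,
PTSD only, PTSD+depression (untreated), depression only (untreated),
depression on second-line SSRI, PTSD+depression on second-line SSRI, a
three-cycle SSRI continuation tunnel (9 months of supervised medication
after depression remits, one auto-advancing column per cycle), and two
absorbing death states (suicide, other causes).

Structural rules:

* no relapse to PTSD from the well state (recovery from the index trauma
  is permanent; later unrelated traumas are out of scope);
* PTSD+depression cannot transition to depression only — successful PTSD
  treatment also remits co-morbid depression, never the reverse;
* depression is recurrent-remitting: well -> depression (annual recurrence
  probability) and back via SSRI response or spontaneous remission;
* per-cycle suicide hazards depend on the current health state and the
  attained-age band; other-cause mortality depends on age only.

Within a cycle, mortality is applied first and clinical transitions act on
survivors; state membership is valued at the cycle midpoint (half-cycle
correction) and discounted continuously in quarter-year steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet, to_per_cycle
from .tree import (EndStateDistribution, StrategyDefinition, evaluate_tree,
                   default_strategies)

# state indices
WELL, PTSD, PTSD_DEP, DEP, DEP_SSRI, PTSD_DEP_SSRI = 0, 1, 2, 3, 4, 5
TUN1, TUN2, TUN3 = 6, 7, 8
DEATH_SUICIDE, DEATH_OTHER = 9, 10
N_STATES = 11

STATE_NAMES = ("well", "ptsd_only", "ptsd_dep", "dep_only", "dep_only_on_ssri",
               "ptsd_dep_on_ssri", "ssri_tunnel_1", "ssri_tunnel_2",
               "ssri_tunnel_3", "death_suicide", "death_other")

ALIVE = tuple(range(9))
SSRI_STATES = (DEP_SSRI, PTSD_DEP_SSRI, TUN1, TUN2, TUN3)

# suicide-hazard group of each alive state
_SUICIDE_GROUP = {
    WELL: "general", TUN1: "general", TUN2: "general", TUN3: "general",
    PTSD: "ptsd_only",
    PTSD_DEP: "ptsd_dep", PTSD_DEP_SSRI: "ptsd_dep",
    DEP: "dep_only", DEP_SSRI: "dep_only",
}


class SimplexError(ValueError):
    """Initial distribution is not a probability vector."""


def _age_at_cycle(cycle: int, params: ParameterSet) -> float:
    # tree covers year 1; Markov cycle 0 starts at age baseline+1
    return params.settings.baseline_age_years + 1 + cycle / params.settings.cycles_per_year


def _year_since_baseline(cycle: int, params: ParameterSet) -> int:
    # the year of life (since baseline) a cycle belongs to: cycle 0 -> year 2
    return 2 + cycle // params.settings.cycles_per_year


def build_transition_matrix(cycle_index: int, params: ParameterSet,
                            treated_fraction: float = 1.0) -> np.ndarray:
    """Per-cycle transition matrix for a given cycle of the Markov phase.

    ``treated_fraction`` is the share of new/persisting depression managed
    with second-line SSRI (1 for the treated arms, 0 for the untreated
    comparator, which never contacts the care system).
    """
    n_cycles = params.settings.n_cycles
    if not 0 <= cycle_index < n_cycles:
        raise IndexError(f"cycle {cycle_index} outside [0, {n_cycles})")

    pw, eff, mo = params.pathways, params.effectiveness, params.mortality
    # re-occurrence of depression: the point estimate is read as the
    # probability of ever relapsing over the modelled horizon (see
    # docs/methods.md) unless configured as a 12-month probability
    rec_cycles = n_cycles if params.settings.recurrence_over_horizon else 4
    p_rec = to_per_cycle(pw.p_dep_recurrence, rec_cycles)
    p_spont = to_per_cycle(pw.p_dep_spont_remission)
    p_ssri = to_per_cycle(eff.p_ssri_depression * params.settings.ssri_compliance)
    p_ptsd_rec = pw.recovery_rate_for_year(_year_since_baseline(cycle_index, params))

    band = mo.band_index(_age_at_cycle(cycle_index, params))

    # clinical kernel among survivors
    K = np.zeros((N_STATES, N_STATES))
    K[WELL, DEP_SSRI] = p_rec * treated_fraction
    K[WELL, DEP] = p_rec * (1.0 - treated_fraction)
    K[WELL, WELL] = 1.0 - p_rec
    K[PTSD, WELL] = p_ptsd_rec
    K[PTSD, PTSD] = 1.0 - p_ptsd_rec
    K[PTSD_DEP, PTSD] = p_spont
    K[PTSD_DEP, PTSD_DEP] = 1.0 - p_spont
    K[DEP, WELL] = p_spont
    K[DEP, DEP] = 1.0 - p_spont
    K[DEP_SSRI, TUN1] = p_ssri
    K[DEP_SSRI, DEP_SSRI] = 1.0 - p_ssri
    K[PTSD_DEP_SSRI, PTSD] = p_ssri
    K[PTSD_DEP_SSRI, PTSD_DEP_SSRI] = 1.0 - p_ssri
    K[TUN1, TUN2] = 1.0
    K[TUN2, TUN3] = 1.0
    K[TUN3, WELL] = 1.0

    M = np.zeros((N_STATES, N_STATES))
    p_other = float(mo.other_cause[band])
    for s in ALIVE:
        p_sui = float(mo.suicide[_SUICIDE_GROUP[s]][band])
        M[s] = (1.0 - p_sui - p_other) * K[s]
        M[s, DEATH_SUICIDE] += p_sui
        M[s, DEATH_OTHER] += p_other
    M[DEATH_SUICIDE, DEATH_SUICIDE] = 1.0
    M[DEATH_OTHER, DEATH_OTHER] = 1.0
    return M


def cycle_matrices(params: ParameterSet,
                   treated_fraction: float = 1.0) -> np.ndarray:
    """All per-cycle transition matrices, shape (n_cycles, 11, 11).

    Only a handful of (recovery-band, age-band) combinations are distinct,
    so unique matrices are built once and broadcast over cycles.
    """
    n = params.settings.n_cycles
    keys = [(_year_since_baseline(c, params),
             params.mortality.band_index(_age_at_cycle(c, params)))
            for c in range(n)]
    # recovery rate only changes with its year band; collapse the key
    rate_keys = [(params.pathways.recovery_rate_for_year(y), b) for y, b in keys]
    unique: dict[tuple[float, int], np.ndarray] = {}
    for c, k in enumerate(rate_keys):
        if k not in unique:
            unique[k] = build_transition_matrix(c, params, treated_fraction)
    return np.stack([unique[k] for k in rate_keys])


def utility_vector(cycle: int, params: ParameterSet) -> np.ndarray:
    """State utilities for one cycle; the well/tunnel utility drops from
    0.87 to 0.85 when the cohort turns 30."""
    ut = params.utilities
    u_well = ut.u_well_30_40 if _age_at_cycle(cycle, params) >= 30 else ut.u_well_10_30
    u = np.zeros(N_STATES)
    u[[WELL, TUN1, TUN2, TUN3]] = u_well
    u[PTSD] = ut.u_ptsd
    u[[PTSD_DEP, PTSD_DEP_SSRI]] = ut.u_ptsd_dep
    u[[DEP, DEP_SSRI]] = ut.u_dep
    return u


def cost_vector(params: ParameterSet) -> np.ndarray:
    """Per-cycle cost by state: a 3-month sertraline supply plus one GP
    monitoring/renewal visit while in any on-SSRI or continuation state."""
    c = np.zeros(N_STATES)
    per_cycle = (params.settings.cycle_length_months * params.costs.sertraline_month
                 + params.costs.gp_consult)
    c[list(SSRI_STATES)] = per_cycle
    return c


@dataclass
class MarkovTrace:
    """Cohort occupancy and discounted accruals over all cycles."""

    occupancy: np.ndarray  # (n_cycles + 1, 11), row 0 = initial distribution
    disc_qaly: np.ndarray  # (n_cycles,)
    disc_cost: np.ndarray  # (n_cycles,)

    @property
    def total_qalys(self) -> float:
        return float(self.disc_qaly.sum())

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.disc_qaly.shape[0]
        recs = []
        for c in range(n):
            for s, name in enumerate(STATE_NAMES):
                recs.append({"cycle": c, "state": name,
                             "occupancy": self.occupancy[c + 1, s]})
        df = pd.DataFrame(recs)
        acc = pd.DataFrame({"cycle": range(n), "discounted_qaly": self.disc_qaly,
                            "discounted_cost": self.disc_cost})
        return df.merge(acc, on="cycle")


def initial_vector(initial: EndStateDistribution,
                   strategy: StrategyDefinition) -> np.ndarray:
    """Map tree end states onto Markov columns.

    Non-responders with baseline depression enter the second-line-SSRI
    state in arms with care-system access, the untreated PTSD+depression
    state otherwise.
    """
    vec = np.zeros(N_STATES)
    vec[WELL] = initial.share_well
    vec[PTSD] = initial.share_ptsd_only
    dep_state = PTSD_DEP_SSRI if strategy.second_line_ssri else PTSD_DEP
    vec[dep_state] = initial.share_ptsd_dep
    return vec


def discount_factors(params: ParameterSet) -> np.ndarray:
    """Midpoint discount factor per Markov cycle; cycle c sits
    1 + (c + 0.5)/4 years after baseline."""
    r = params.settings.discount_rate_annual
    cyc = np.arange(params.settings.n_cycles)
    years = 1.0 + (cyc + 0.5) / params.settings.cycles_per_year
    return (1.0 + r) ** -years


def run_cohort(initial, params: ParameterSet,
               strategy: StrategyDefinition | None = None,
               matrices: np.ndarray | None = None) -> MarkovTrace:
    """Propagate a cohort through all cycles with half-cycle correction.

    ``initial`` is an :class:`EndStateDistribution` (requires ``strategy``)
    or an 11-vector over Markov columns.
    """
    if isinstance(initial, EndStateDistribution):
        if strategy is None:
            raise ValueError("strategy required to route tree end states")
        occ0 = initial_vector(initial, strategy)
    else:
        occ0 = np.asarray(initial, dtype=float)
    if occ0.shape != (N_STATES,) or occ0.min() < -1e-12 \
            or abs(occ0.sum() - 1.0) > 1e-9:
        raise SimplexError(f"initial distribution invalid (sum {occ0.sum()})")

    treated = 1.0 if strategy is None or strategy.second_line_ssri else 0.0
    if matrices is None:
        matrices = cycle_matrices(params, treated)
    n = params.settings.n_cycles
    disc = discount_factors(params)
    cvec = cost_vector(params)
    cycle_frac = params.settings.cycle_length_months / 12.0

    occupancy = np.empty((n + 1, N_STATES))
    occupancy[0] = occ0
    occ = occ0
    for c in range(n):
        occ = occ @ matrices[c]
        occupancy[c + 1] = occ

    # half-cycle-corrected accruals, vectorised over cycles
    mids = 0.5 * (occupancy[:-1] + occupancy[1:])
    cutoff = n
    for c in range(n):
        if _age_at_cycle(c, params) >= 30:
            cutoff = c
            break
    U = np.empty((n, N_STATES))
    U[:cutoff] = utility_vector(0, params)
    if cutoff < n:
        U[cutoff:] = utility_vector(cutoff, params)
    disc_qaly = cycle_frac * (mids * U).sum(axis=1) * disc
    disc_cost = (mids @ cvec) * disc
    return MarkovTrace(occupancy, disc_qaly, disc_cost)


@dataclass
class EconResult:
    """Combined tree + Markov totals for one strategy."""

    strategy: str
    cost: float
    qaly: float
    cost_year1: float = 0.0
    qaly_year1: float = 0.0

    @property
    def cost_markov(self) -> float:
        return self.cost - self.cost_year1

    @property
    def qaly_markov(self) -> float:
        return self.qaly - self.qaly_year1


def evaluate_strategy(strategy: StrategyDefinition,
                      params: ParameterSet) -> EconResult:
    """Full 31-year evaluation of one arm: 12-month tree, then 120 Markov
    cycles seeded with the tree's end-state distribution."""
    tr = evaluate_tree(strategy, params)
    trace = run_cohort(tr.end_states, params, strategy)
    return EconResult(
        strategy=strategy.name,
        cost=tr.cost_year1 + trace.total_cost,
        qaly=tr.qaly_year1 + trace.total_qalys,
        cost_year1=tr.cost_year1,
        qaly_year1=tr.qaly_year1,
    )


def evaluate_all(params: ParameterSet,
                 strategies: list[StrategyDefinition] | None = None
                 ) -> list[EconResult]:
    strategies = strategies or default_strategies(params)
    return [evaluate_strategy(s, params) for s in strategies]
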