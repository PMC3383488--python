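"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-evaluates the whole model at the low and high end of a
parameter's range (printed ranges where available, otherwise +/-30% of the
point estimate), all else held at point values.  Two pre-defined two-way
analyses jointly perturb the TF-CBT / TF-CBT+SSRI effectiveness pair (to
respect their covariance: one is a component of the other) and the
PTSD+depression / depression-only utility pair.  The probabilistic
analysis draws every parameter carrying a Beta (probabilities) or Gamma
(costs, disease utilities) specification independently per trial and
reports means with 2.5/97.5 percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import build_cea_table
from .markov import EconResult, evaluate_all
from .params import ParameterSet, psa_parameter_ids, dsa_parameter_ids
from .tree import StrategyDefinition, default_strategies

# the two pre-defined joint perturbations
EFFECTIVENESS_PAIR = ("p_response_tfcbt", "p_response_tfcbt_ssri")
UTILITY_PAIR = ("u_ptsd_dep", "u_dep")

_UTILITY_IDS = frozenset({"u_ptsd", "u_ptsd_dep", "u_dep"})


@dataclass
class DSARecord:
    """One full model evaluation under a deterministic perturbation."""

    param_id: str
    level: str  # "low" | "high" | "point" | custom
    values: dict[str, float]
    results: list[EconResult]
    table: pd.DataFrame


def _evaluate(params: ParameterSet, strategies=None,
              comparator: str = "no_treatment"):
    strategies = strategies or default_strategies(params)
    results = evaluate_all(params, strategies)
    return results, build_cea_table(results, comparator=comparator)


def _strategies_at(params: ParameterSet):
    # effectiveness perturbations must reach the strategy definitions
    return default_strategies(params)


def one_way(param_id: str, params: ParameterSet,
            comparator: str = "no_treatment") -> tuple[DSARecord, DSARecord]:
    """Evaluate the model at the low and high end of one parameter."""
    registry = params.parameters()
    if param_id not in registry:
        raise KeyError(f"unknown parameter id {param_id!r}")
    p = registry[param_id]
    out = []
    for level, value in (("low", p.low), ("high", p.high)):
        perturbed = params.with_values({param_id: value})
        results, table = _evaluate(perturbed, _strategies_at(perturbed),
                                   comparator)
        out.append(DSARecord(param_id, level, {param_id: value}, results, table))
    return out[0], out[1]


def dsa_all(params: ParameterSet,
            comparator: str = "no_treatment") -> pd.DataFrame:
    """Tidy one-way DSA over every eligible parameter.

    One row per (parameter, level, strategy) with totals, the ICER versus
    the comparator and the dominance flag.
    """
    rows = []
    for pid in dsa_parameter_ids(params):
        for rec in one_way(pid, params, comparator):
            for _, trow in rec.table.iterrows():
                rows.append({
                    "param_id": pid, "level": rec.level,
                    "value": rec.values[pid],
                    "strategy": trow["strategy"],
                    "cost": trow["cost"], "qaly": trow["qaly"],
                    "icer_vs_comparator": trow["icer_vs_comparator"],
                    "dominance": trow["dominance"],
                })
    return pd.DataFrame(rows)


def two_way(param_ids: tuple[str, str], levels, params: ParameterSet,
            comparator: str = "no_treatment") -> DSARecord:
    """Joint perturbation of a parameter pair, one evaluation.

    ``levels`` is a pair of "low"/"high"/"point" labels or explicit values.
    """
    registry = params.parameters()
    updates: dict[str, float] = {}
    for pid, level in zip(param_ids, levels):
        if pid not in registry:
            raise KeyError(f"unknown parameter id {pid!r}")
        p = registry[pid]
        if isinstance(level, str):
            updates[pid] = {"low": p.low, "high": p.high, "point": p.point}[level]
        else:
            updates[pid] = float(level)
    perturbed = params.with_values(updates)
    results, table = _evaluate(perturbed, _strategies_at(perturbed), comparator)
    label = "+".join(str(l) for l in levels)
    return DSARecord("+".join(param_ids), label, updates, results, table)


@dataclass
class PSAResult:
    """Monte-Carlo draws over strategies with summary statistics."""

    draws: pd.DataFrame  # columns: trial, strategy, cost, qaly
    means: pd.DataFrame  # index strategy, columns cost, qaly
    ci: pd.DataFrame  # index strategy, columns cost_lo/hi, qaly_lo/hi
    seed: int
    n_trials: int

    def summary(self, comparator: str = "no_treatment") -> pd.DataFrame:
        """Per-strategy means, percentile intervals and mean-based ICERs."""
        from .cea import icer
        base = self.means.loc[comparator]
        rows = []
        for strat, m in self.means.iterrows():
            rows.append({
                "strategy": strat,
                "mean_cost": m["cost"], "mean_qaly": m["qaly"],
                "cost_ci_lower": self.ci.loc[strat, "cost_lo"],
                "cost_ci_upper": self.ci.loc[strat, "cost_hi"],
                "qaly_ci_lower": self.ci.loc[strat, "qaly_lo"],
                "qaly_ci_upper": self.ci.loc[strat, "qaly_hi"],
                "inc_qaly_vs_comparator": m["qaly"] - base["qaly"],
                "icer_vs_comparator": (np.nan if strat == comparator else
                                       icer(m["cost"], m["qaly"],
                                            base["cost"], base["qaly"])),
            })
        return pd.DataFrame(rows)


def sample_parameter_set(params: ParameterSet, rng: np.random.Generator,
                         sampled_ids: list[str] | None = None) -> ParameterSet:
    """One PSA draw: independent Beta/Gamma sampling of the distributed
    parameters; utility draws above 1 are clamped (negligible Gamma mass)."""
    if sampled_ids is None:
        sampled_ids = psa_parameter_ids(params)
    registry = params.parameters()
    updates: dict[str, float] = {}
    for pid in sampled_ids:
        dist = registry[pid].dist
        if dist is None or dist.family == "fixed":
            raise ValueError(f"parameter {pid!r} has no sampling distribution")
        if dist.family == "beta":
            val = float(rng.beta(dist.alpha, dist.beta_or_rate))
        else:
            val = float(rng.gamma(dist.alpha, 1.0 / dist.beta_or_rate))
        if pid in _UTILITY_IDS and val > 1.0:
            warnings.warn(f"clamped sampled utility {pid} = {val:.4f} to 1.0",
                          RuntimeWarning, stacklevel=2)
            val = 1.0
        updates[pid] = val
    return params.with_values(updates)


def psa(params: ParameterSet, n_trials: int | None = None,
        seed: int | None = None, ci_level: float = 0.95) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each trial draws all distributed parameters, re-derives the strategy
    definitions (sampled response probabilities feed the decision tree)
    and evaluates all four arms.  One RNG substream per trial keeps trials
    replayable independently of execution order.
    """
    if n_trials is None:
        n_trials = params.settings.psa_trials
    if seed is None:
        seed = params.settings.rng_seed
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sampled_ids = psa_parameter_ids(params)
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    records = []
    for trial, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        drawn = sample_parameter_set(params, rng, sampled_ids)
        for res in evaluate_all(drawn, default_strategies(drawn)):
            records.append((trial, res.strategy, res.cost, res.qaly))
    draws = pd.DataFrame(records, columns=["trial", "strategy", "cost", "qaly"])
    means = draws.groupby("strategy")[["cost", "qaly"]].mean()
    alpha = (1.0 - ci_level) / 2.0
    qlo, qhi = draws.groupby("strategy")[["cost", "qaly"]].quantile(alpha), \
        draws.groupby("strategy")[["cost", "qaly"]].quantile(1.0 - alpha)
    ci = pd.DataFrame({
        "cost_lo": qlo["cost"], "cost_hi": qhi["cost"],
        "qaly_lo": qlo["qaly"], "qaly_hi": qhi["qaly"],
    })
    return PSAResult(draws, means, ci, seed=seed, n_trials=n_trials)
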