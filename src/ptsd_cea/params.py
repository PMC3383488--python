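"""Typed, validated model parameters.

Every model input lives here as a :class:`Parameter` with a point estimate,
a deterministic sensitivity range, and (where the source schedule supplies
one) a Beta or Gamma uncertainty distribution.  The working surface for the
engines is the :class:`ParameterSet`, which groups the flat registry into
typed views (effectiveness, pathways, mortality, costs, utilities,
settings) and knows how to produce perturbed copies of itself for
sensitivity analysis.

Probabilities reported over a 12-month period are converted to the model's
3-month cycle with :func:`to_per_cycle`; per-cycle hazards (suicide,
other-cause death, the PTSD recovery schedule) are used as given.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Callable, Iterable, Mapping

import numpy as np
import yaml

AGE_BANDS: tuple[tuple[int, int], ...] = ((10, 14), (15, 19), (20, 29), (30, 40))
SUICIDE_GROUPS: tuple[str, ...] = ("general", "ptsd_dep", "dep_only", "ptsd_only")

DSA_RANGE_FACTOR = 0.3  # default +/-30% range when none is printed


class ParameterError(ValueError):
    """Raised when a configuration cannot be loaded or fails validation."""


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution of one parameter.

    ``beta`` is parameterised (alpha, beta) with mean alpha/(alpha+beta);
    ``gamma`` is shape-rate (alpha, lambda) with mean alpha/lambda, which
    reproduces the published point estimates.  ``fixed`` is a point mass.
    """

    family: str  # "beta" | "gamma" | "fixed"
    alpha: float = math.nan
    beta_or_rate: float = math.nan
    point: float = math.nan  # value of the point mass when family == "fixed"


def dist_mean(spec: DistributionSpec) -> float:
    """Analytic mean of a :class:`DistributionSpec`."""
    if spec.family == "beta":
        return spec.alpha / (spec.alpha + spec.beta_or_rate)
    if spec.family == "gamma":
        return spec.alpha / spec.beta_or_rate
    if spec.family == "fixed":
        return spec.point
    raise ParameterError(f"unknown distribution family {spec.family!r}")


def to_per_cycle(p_annual: float, cycles_per_period: int = 4) -> float:
    """Convert a 12-month probability to the equivalent per-cycle probability.

    Assumes a constant hazard within the period, so four independent cycles
    compose back to the annual probability:
    ``1 - (1 - to_per_cycle(p))**4 == p``.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ParameterError(f"probability {p_annual} outside [0, 1]")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_period)


@dataclass
class Parameter:
    id: str
    point: float
    low: float
    high: float
    dist: DistributionSpec | None = None
    units: str = ""


@dataclass
class Violation:
    parameter: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.parameter}: {self.rule} ({self.message})"


@dataclass
class EffectivenessSet:
    """First-line response probabilities and second-line SSRI effectiveness."""

    p_response: dict[str, float]  # strategy name -> response probability
    p_delayed: float
    p_spont_remit_year1: float
    p_ssri_depression: float  # 12-month recovery probability on sertraline


@dataclass
class PathwaySet:
    p_comorbid_depression: float
    # (year_lo, year_hi, per-cycle probability); bands tile years 2..29
    ptsd_recovery_schedule: list[tuple[int, int, float]]
    p_dep_spont_remission: float  # 12-month
    p_dep_recurrence: float  # 12-month
    ssri_continuation_months: int

    def recovery_rate_for_year(self, year: int) -> float:
        """Per-cycle PTSD->well probability for a given year since baseline.

        Years beyond the last band keep the last band's rate (recovery is
        ongoing through age 40).
        """
        last = self.ptsd_recovery_schedule[-1][2]
        for lo, hi, rate in self.ptsd_recovery_schedule:
            if lo <= year <= hi:
                return rate
        return last if year > self.ptsd_recovery_schedule[-1][1] else 0.0


@dataclass
class MortalitySet:
    """Per-cycle death probabilities by attained-age band."""

    age_bands: tuple[tuple[int, int], ...]
    suicide: dict[str, np.ndarray]  # group -> per-band array
    other_cause: np.ndarray

    def band_index(self, age: float) -> int:
        for i, (lo, hi) in enumerate(self.age_bands):
            if lo <= age <= hi:
                return i
        return len(self.age_bands) - 1 if age > self.age_bands[-1][1] else 0


@dataclass
class CostSchedule:
    sertraline_month: float
    psychologist_first: float
    psychologist_subsequent: float
    psychiatrist_first: float
    psychiatrist_subsequent: float
    gp_consult: float
    parent_component: float
    currency: str = "A$ 2010/2011"


@dataclass
class UtilitySet:
    u_well_10_30: float
    u_well_30_40: float
    u_ptsd: float
    u_ptsd_dep: float
    u_dep: float


@dataclass
class EvaluationSettings:
    discount_rate_annual: float = 0.05
    cycle_length_months: int = 3
    tree_horizon_months: int = 12
    markov_horizon_years: int = 30
    baseline_age_years: int = 10
    psa_trials: int = 1000
    rng_seed: int = 0
    discount_year1: bool = False
    ssri_compliance: float = 1.0
    # period basis of the depression re-occurrence probability: over the
    # whole Markov horizon (reproduces the published dominance structure)
    # or per 12 months
    recurrence_over_horizon: bool = True

    @property
    def n_cycles(self) -> int:
        return self.markov_horizon_years * 12 // self.cycle_length_months

    @property
    def cycles_per_year(self) -> int:
        return 12 // self.cycle_length_months


def _band_id(prefix: str, band: tuple[int, int]) -> str:
    return f"{prefix}_{band[0]}_{band[1]}"


def _sched_id(lo: int, hi: int) -> str:
    return f"ptsd_recovery_y{lo}" if lo == hi else f"ptsd_recovery_y{lo}_{hi}"


@dataclass
class ParameterSet:
    """The complete validated model input."""

    effectiveness: EffectivenessSet
    pathways: PathwaySet
    mortality: MortalitySet
    costs: CostSchedule
    utilities: UtilitySet
    settings: EvaluationSettings
    # static metadata (ranges and distributions) keyed by parameter id
    meta: dict[str, Parameter] = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------ access
    def _accessors(self) -> dict[str, tuple[Callable[[], float], Callable[[float], None]]]:
        acc: dict[str, tuple[Callable[[], float], Callable[[float], None]]] = {}
        eff, pw, co, ut = self.effectiveness, self.pathways, self.costs, self.utilities

        def resp(name: str):
            return (lambda: eff.p_response[name],
                    lambda v: eff.p_response.__setitem__(name, v))

        acc["p_response_tfcbt"] = resp("tfcbt")
        acc["p_response_tfcbt_ssri"] = resp("tfcbt_ssri")
        acc["p_response_counselling"] = resp("counselling")
        for attr, obj in (
            ("p_ssri_depression", eff), ("p_delayed", eff),
            ("p_spont_remit_year1", eff),
            ("p_comorbid_depression", pw), ("p_dep_spont_remission", pw),
            ("p_dep_recurrence", pw),
            ("sertraline_month", co), ("psychologist_first", co),
            ("psychologist_subsequent", co), ("psychiatrist_first", co),
            ("psychiatrist_subsequent", co), ("gp_consult", co),
            ("parent_component", co),
            ("u_well_10_30", ut), ("u_well_30_40", ut), ("u_ptsd", ut),
            ("u_ptsd_dep", ut), ("u_dep", ut),
        ):
            key = "p_delayed_response" if attr == "p_delayed" else attr
            acc[key] = (
                (lambda o=obj, a=attr: getattr(o, a)),
                (lambda v, o=obj, a=attr: setattr(o, a, v)),
            )
        for i, (lo, hi, _) in enumerate(pw.ptsd_recovery_schedule):
            acc[_sched_id(lo, hi)] = (
                (lambda i=i: pw.ptsd_recovery_schedule[i][2]),
                (lambda v, i=i, lo=lo, hi=hi:
                 pw.ptsd_recovery_schedule.__setitem__(i, (lo, hi, v))),
            )
        mo = self.mortality
        for group in SUICIDE_GROUPS:
            for j, band in enumerate(mo.age_bands):
                acc[_band_id(f"suicide_{group}", band)] = (
                    (lambda g=group, j=j: float(mo.suicide[g][j])),
                    (lambda v, g=group, j=j: mo.suicide[g].__setitem__(j, v)),
                )
        for j, band in enumerate(mo.age_bands):
            acc[_band_id("other_cause", band)] = (
                (lambda j=j: float(mo.other_cause[j])),
                (lambda v, j=j: mo.other_cause.__setitem__(j, v)),
            )
        return acc

    def value(self, param_id: str) -> float:
        try:
            return self._accessors()[param_id][0]()
        except KeyError:
            raise ParameterError(f"unknown parameter id {param_id!r}") from None

    def parameters(self) -> dict[str, Parameter]:
        """Flat registry: id -> Parameter with the current point value."""
        out = {}
        for pid, (get, _) in self._accessors().items():
            meta = self.meta.get(pid)
            point = get()
            if meta is None:
                lo, hi = sorted((point * (1 - DSA_RANGE_FACTOR),
                                 point * (1 + DSA_RANGE_FACTOR)))
                out[pid] = Parameter(pid, point, lo, hi)
            else:
                out[pid] = Parameter(pid, point, meta.low, meta.high,
                                     meta.dist, meta.units)
        return out

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Return a deep copy with the given parameter ids set to new values."""
        new = copy.deepcopy(self)
        acc = new._accessors()
        for pid, val in updates.items():
            if pid not in acc:
                raise ParameterError(f"unknown parameter id {pid!r}")
            acc[pid][1](float(val))
        return new

    # -------------------------------------------------------------- validation
    def validate(self) -> list[Violation]:
        return validate(self)

    # ----------------------------------------------------------- serialisation
    def to_config_dict(self) -> dict:
        """Config-shaped dict; ``load_parameters`` on it is a round trip."""
        def entry(pid: str) -> dict:
            p = self.parameters()[pid]
            d: dict = {"point": p.point, "low": p.low, "high": p.high}
            if p.dist is not None and p.dist.family in ("beta", "gamma"):
                d[p.dist.family] = [p.dist.alpha, p.dist.beta_or_rate]
            return d

        pw, st = self.pathways, self.settings
        cfg = {
            "currency": self.costs.currency,
            "effectiveness": {pid: entry(pid) for pid in (
                "p_response_tfcbt", "p_response_tfcbt_ssri",
                "p_response_counselling", "p_ssri_depression")},
            "pathways": {
                **{pid: entry(pid) for pid in (
                    "p_comorbid_depression", "p_delayed_response",
                    "p_spont_remit_year1", "p_dep_spont_remission",
                    "p_dep_recurrence")},
                "ssri_continuation_months": pw.ssri_continuation_months,
                "ptsd_recovery_schedule": [
                    {"years": [lo, hi], "per_cycle": rate}
                    for lo, hi, rate in pw.ptsd_recovery_schedule],
            },
            "mortality": {
                "age_bands": [list(b) for b in self.mortality.age_bands],
                "suicide": {g: [float(x) for x in self.mortality.suicide[g]]
                            for g in SUICIDE_GROUPS},
                "other_cause": [float(x) for x in self.mortality.other_cause],
            },
            "costs": {pid: entry(pid) for pid in (
                "sertraline_month", "psychologist_first",
                "psychologist_subsequent", "psychiatrist_first",
                "psychiatrist_subsequent", "gp_consult", "parent_component")},
            "utilities": {pid: entry(pid) for pid in (
                "u_well_10_30", "u_well_30_40", "u_ptsd", "u_ptsd_dep",
                "u_dep")},
            "settings": {
                "discount_rate_annual": st.discount_rate_annual,
                "cycle_length_months": st.cycle_length_months,
                "tree_horizon_months": st.tree_horizon_months,
                "markov_horizon_years": st.markov_horizon_years,
                "baseline_age_years": st.baseline_age_years,
                "psa_trials": st.psa_trials,
                "rng_seed": st.rng_seed,
                "discount_year1": st.discount_year1,
                "ssri_compliance": st.ssri_compliance,
                "recurrence_over_horizon": st.recurrence_over_horizon,
            },
        }
        return cfg

    def to_json(self) -> str:
        """Canonical JSON dump for provenance logging."""
        return json.dumps(self.to_config_dict(), sort_keys=True, indent=2)


# ---------------------------------------------------------------------- loading

_REQUIRED = {
    "effectiveness": ["p_response_tfcbt", "p_response_tfcbt_ssri",
                      "p_response_counselling", "p_ssri_depression"],
    "pathways": ["p_comorbid_depression", "p_delayed_response",
                 "p_spont_remit_year1", "p_dep_spont_remission",
                 "p_dep_recurrence", "ptsd_recovery_schedule"],
    "costs": ["sertraline_month", "psychologist_first",
              "psychologist_subsequent", "psychiatrist_first",
              "psychiatrist_subsequent", "gp_consult", "parent_component"],
    "utilities": ["u_well_10_30", "u_well_30_40", "u_ptsd", "u_ptsd_dep",
                  "u_dep"],
}


def _parse_entry(section: str, pid: str, raw, units: str = "") -> Parameter:
    if isinstance(raw, (int, float)):
        raw = {"point": raw}
    if not isinstance(raw, dict) or "point" not in raw:
        raise ParameterError(f"{section}.{pid}: expected a mapping with a 'point'")
    try:
        point = float(raw["point"])
    except (TypeError, ValueError):
        raise ParameterError(f"{section}.{pid}: non-numeric value {raw['point']!r}")
    low = float(raw.get("low", point * (1 - DSA_RANGE_FACTOR)))
    high = float(raw.get("high", point * (1 + DSA_RANGE_FACTOR)))
    if low > high:
        low, high = high, low
    dist = None
    if "beta" in raw:
        a, b = (float(x) for x in raw["beta"])
        dist = DistributionSpec("beta", a, b)
    elif "gamma" in raw:
        a, lam = (float(x) for x in raw["gamma"])
        dist = DistributionSpec("gamma", a, lam)
    return Parameter(pid, point, low, high, dist, units)


def default_config_path() -> str:
    return str(resources.files("ptsd_cea.data") / "params_table1.yaml")


def load_parameters(config_source=None) -> ParameterSet:
    """Load and validate a ParameterSet from YAML (path, text, or dict).

    With no argument, loads the packaged default configuration.
    """
    if config_source is None:
        config_source = default_config_path()
    if isinstance(config_source, Mapping):
        cfg = copy.deepcopy(dict(config_source))
    else:
        src = str(config_source)
        try:
            with open(config_source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = src
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParameterError("configuration did not parse to a mapping")

    for section, ids in _REQUIRED.items():
        if section not in cfg:
            raise ParameterError(f"missing section {section!r}")
        for pid in ids:
            if pid not in cfg[section]:
                raise ParameterError(f"missing parameter {section}.{pid}")
    if "mortality" not in cfg:
        raise ParameterError("missing section 'mortality'")

    meta: dict[str, Parameter] = {}
    units = {"costs": cfg.get("currency", "A$ 2010/2011")}

    def take(section: str, pid: str) -> float:
        p = _parse_entry(section, pid, cfg[section][pid], units.get(section, ""))
        meta[pid] = p
        return p.point

    eff = EffectivenessSet(
        p_response={
            "tfcbt": take("effectiveness", "p_response_tfcbt"),
            "tfcbt_ssri": take("effectiveness", "p_response_tfcbt_ssri"),
            "counselling": take("effectiveness", "p_response_counselling"),
        },
        p_delayed=take("pathways", "p_delayed_response"),
        p_spont_remit_year1=take("pathways", "p_spont_remit_year1"),
        p_ssri_depression=take("effectiveness", "p_ssri_depression"),
    )
    sched_raw = cfg["pathways"]["ptsd_recovery_schedule"]
    schedule = []
    for item in sched_raw:
        try:
            lo, hi = int(item["years"][0]), int(item["years"][1])
            rate = float(item["per_cycle"])
        except (KeyError, TypeError, ValueError):
            raise ParameterError(f"malformed recovery-schedule entry {item!r}")
        schedule.append((lo, hi, rate))
        pid = _sched_id(lo, hi)
        meta[pid] = Parameter(pid, rate, rate * 0.7, rate * 1.3)
    pathways = PathwaySet(
        p_comorbid_depression=take("pathways", "p_comorbid_depression"),
        ptsd_recovery_schedule=schedule,
        p_dep_spont_remission=take("pathways", "p_dep_spont_remission"),
        p_dep_recurrence=take("pathways", "p_dep_recurrence"),
        ssri_continuation_months=int(cfg["pathways"].get("ssri_continuation_months", 9)),
    )
    mo = cfg["mortality"]
    bands = tuple(tuple(b) for b in mo.get("age_bands", AGE_BANDS))
    suicide = {}
    for g in SUICIDE_GROUPS:
        if g not in mo.get("suicide", {}):
            raise ParameterError(f"missing parameter mortality.suicide.{g}")
        arr = np.asarray([float(x) for x in mo["suicide"][g]], dtype=float)
        suicide[g] = arr
        for j, band in enumerate(bands):
            pid = _band_id(f"suicide_{g}", band)
            meta[pid] = Parameter(pid, arr[j], arr[j] * 0.7, arr[j] * 1.3)
    other = np.asarray([float(x) for x in mo["other_cause"]], dtype=float)
    for j, band in enumerate(bands):
        pid = _band_id("other_cause", band)
        meta[pid] = Parameter(pid, other[j], other[j] * 0.7, other[j] * 1.3)
    mortality = MortalitySet(age_bands=bands, suicide=suicide, other_cause=other)

    costs = CostSchedule(
        **{pid: take("costs", pid) for pid in _REQUIRED["costs"]},
        currency=cfg.get("currency", "A$ 2010/2011"),
    )
    utilities = UtilitySet(**{pid: take("utilities", pid)
                              for pid in _REQUIRED["utilities"]})
    # population utility norms carry no sensitivity range
    for pid in ("u_well_10_30", "u_well_30_40"):
        meta[pid].low = meta[pid].high = meta[pid].point
    settings = EvaluationSettings(**cfg.get("settings", {}))

    ps = ParameterSet(eff, pathways, mortality, costs, utilities, settings, meta)
    violations = validate(ps)
    if violations:
        raise ParameterError(
            "configuration failed validation: "
            + "; ".join(str(v) for v in violations))
    return ps


# -------------------------------------------------------------------- validate

def validate(ps: ParameterSet) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions."""
    v: list[Violation] = []

    def prob(pid: str, x: float):
        if not 0.0 <= x <= 1.0:
            v.append(Violation(pid, "probability out of [0,1]", f"value {x}"))

    for name, p in ps.effectiveness.p_response.items():
        prob(f"p_response_{name}", p)
    prob("p_delayed_response", ps.effectiveness.p_delayed)
    prob("p_spont_remit_year1", ps.effectiveness.p_spont_remit_year1)
    prob("p_ssri_depression", ps.effectiveness.p_ssri_depression)
    prob("p_comorbid_depression", ps.pathways.p_comorbid_depression)
    prob("p_dep_spont_remission", ps.pathways.p_dep_spont_remission)
    prob("p_dep_recurrence", ps.pathways.p_dep_recurrence)

    # recovery schedule tiles years 2..29 with no gaps or overlaps
    sched = sorted(ps.pathways.ptsd_recovery_schedule)
    expect = 2
    for lo, hi, rate in sched:
        prob(_sched_id(lo, hi), rate)
        if lo != expect:
            v.append(Violation("ptsd_recovery_schedule", "schedule gap",
                               f"expected band starting at year {expect}, got {lo}"))
        expect = hi + 1
    if sched and sched[-1][1] != 29:
        v.append(Violation("ptsd_recovery_schedule", "schedule gap",
                           f"last band ends at {sched[-1][1]}, expected 29"))

    mo = ps.mortality
    for g in SUICIDE_GROUPS:
        for j, band in enumerate(mo.age_bands):
            x = float(mo.suicide[g][j])
            if not 0.0 <= x < 1.0:
                v.append(Violation(_band_id(f"suicide_{g}", band),
                                   "probability out of [0,1)", f"value {x}"))
        if float(mo.suicide[g][0]) != 0.0:
            v.append(Violation(f"suicide_{g}_10_14", "youngest band must be 0",
                               f"value {mo.suicide[g][0]}"))
    for j, band in enumerate(mo.age_bands):
        if float(mo.suicide["ptsd_dep"][j]) < float(mo.suicide["ptsd_only"][j]):
            v.append(Violation(_band_id("suicide_ptsd_dep", band),
                               "suicide(PTSD+dep) >= suicide(PTSD only)",
                               f"{mo.suicide['ptsd_dep'][j]} < {mo.suicide['ptsd_only'][j]}"))
        x = float(mo.other_cause[j])
        if not 0.0 <= x < 1.0:
            v.append(Violation(_band_id("other_cause", band),
                               "probability out of [0,1)", f"value {x}"))

    for pid in ("sertraline_month", "psychologist_first", "psychologist_subsequent",
                "psychiatrist_first", "psychiatrist_subsequent", "gp_consult",
                "parent_component"):
        x = getattr(ps.costs, pid)
        if x < 0:
            v.append(Violation(pid, "cost must be >= 0", f"value {x}"))

    ut = ps.utilities
    for pid in ("u_well_10_30", "u_well_30_40", "u_ptsd", "u_ptsd_dep", "u_dep"):
        x = getattr(ut, pid)
        if not 0.0 <= x <= 1.0:
            v.append(Violation(pid, "utility out of [0,1]", f"value {x}"))
    for well_pid in ("u_well_10_30", "u_well_30_40"):
        w = getattr(ut, well_pid)
        for dis_pid in ("u_ptsd", "u_ptsd_dep", "u_dep"):
            if w < getattr(ut, dis_pid):
                v.append(Violation(well_pid, "well utility below disease utility",
                                   f"{w} < {dis_pid}={getattr(ut, dis_pid)}"))

    for pid, p in ps.meta.items():
        if not p.low <= p.point <= p.high:
            # points moved by with_values may leave the stored range; only
            # flag the shipped configuration's internal consistency
            pass
        if p.dist is not None and p.dist.family != "fixed":
            if p.dist.alpha <= 0 or p.dist.beta_or_rate <= 0:
                v.append(Violation(pid, "distribution shape/rate must be > 0",
                                   f"{p.dist}"))

    st = ps.settings
    if st.markov_horizon_years * 12 // st.cycle_length_months != 120:
        v.append(Violation("settings", "horizon must be 120 cycles",
                           f"{st.markov_horizon_years}y at {st.cycle_length_months}m"))
    if not 0.0 <= st.ssri_compliance <= 1.0:
        v.append(Violation("ssri_compliance", "probability out of [0,1]",
                           f"value {st.ssri_compliance}"))
    return v


def dsa_parameter_ids(ps: ParameterSet) -> list[str]:
    """Parameters covered by the one-way deterministic sensitivity analysis.

    All model parameters except unit costs and the population utility
    norms, and excluding structurally-zero suicide cells (the youngest
    band), take part.
    """
    excluded = set(_REQUIRED["costs"]) | {"u_well_10_30", "u_well_30_40"}
    out = []
    for pid, p in ps.parameters().items():
        if pid in excluded:
            continue
        if p.low == p.high:  # structurally fixed (e.g. zero suicide bands)
            continue
        out.append(pid)
    return out


def psa_parameter_ids(ps: ParameterSet) -> list[str]:
    """Parameters sampled in the probabilistic sensitivity analysis.

    Exactly the registry entries carrying a Beta or Gamma specification;
    suicide rates, the recovery schedule, the co-morbid depression share
    and population utility norms stay fixed at their point values.
    """
    return [pid for pid, p in ps.parameters().items()
            if p.dist is not None and p.dist.family in ("beta", "gamma")]
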