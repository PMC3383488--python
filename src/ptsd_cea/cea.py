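"""Cost-effectiveness analysis: ICERs, dominance, efficiency frontier.

Strategies are ranked by total QALYs; a strategy is strictly dominated if
some alternative costs no more and yields no fewer QALYs (one inequality
strict), and extendedly dominated if a blend of two others beats it along
the cost-effectiveness frontier.  Frontier ICERs are incremental ratios
between successive non-strictly-dominated strategies (the convention of
published league tables); on a convex frontier they increase
monotonically, and a violation of that monotonicity is exactly what the
extended-dominance flag marks.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .markov import EconResult

def load_reference_totals() -> dict[str, list[dict]]:
    """Published worked-example totals (short- and long-term) shipped with
    the package, as build_cea_table-ready row lists keyed by horizon."""
    path = resources.files("ptsd_cea.data") / "reference_results.yaml"
    raw = yaml.safe_load(path.read_text())
    return {horizon: [{"strategy": name, **vals}
                      for name, vals in rows.items()]
            for horizon, rows in raw.items()}


NO_DOMINANCE = "none"
STRICT = "strictly_dominated"
EXTENDED = "extendedly_dominated"


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> float:
    """Incremental cost-effectiveness ratio of A versus B.

    Returns NaN when the QALY difference is zero (undefined ICER).
    """
    dq = qaly_a - qaly_b
    if dq == 0.0:
        return math.nan
    return (cost_a - cost_b) / dq


def _strictly_dominated(row, others) -> bool:
    for o in others:
        if o is row:
            continue
        if (o["cost"] <= row["cost"] and o["qaly"] >= row["qaly"]
                and (o["cost"] < row["cost"] or o["qaly"] > row["qaly"])):
            return True
    return False


def build_cea_table(results: Sequence[EconResult] | Iterable,
                    comparator: str = "no_treatment",
                    wtp_threshold: float | None = 50_000.0) -> pd.DataFrame:
    """CEA table: ICERs vs the comparator, dominance flags, frontier ICERs.

    ``results`` may be EconResults or (strategy, cost, qaly) mappings.
    Incremental columns are derived from the totals at full precision.
    """
    rows = []
    for r in results:
        if isinstance(r, EconResult):
            rows.append({"strategy": r.strategy, "cost": r.cost, "qaly": r.qaly})
        else:
            rows.append({"strategy": r["strategy"], "cost": float(r["cost"]),
                         "qaly": float(r["qaly"])})
    names = [r["strategy"] for r in rows]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    if comparator not in names:
        raise ValueError(f"comparator {comparator!r} not among strategies")
    if len(rows) < 2:
        raise ValueError("need at least two strategies")

    rows.sort(key=lambda r: (r["qaly"], -r["cost"]))
    base = next(r for r in rows if r["strategy"] == comparator)

    for r in rows:
        r["dominance"] = STRICT if _strictly_dominated(r, rows) else NO_DOMINANCE

    # frontier ICERs are computed between successive non-strictly-dominated
    # strategies (the published-table convention); extended dominance — a
    # strategy whose incremental ICER exceeds the next one's, i.e. a blend
    # of its neighbours beats it — is flagged as an annotation on top
    chain = [r for r in rows if r["dominance"] == NO_DOMINANCE]
    convex = list(chain)
    changed = True
    while changed and len(convex) > 2:
        changed = False
        for i in range(1, len(convex) - 1):
            lo, mid, hi = convex[i - 1], convex[i], convex[i + 1]
            icer_lo = icer(mid["cost"], mid["qaly"], lo["cost"], lo["qaly"])
            icer_hi = icer(hi["cost"], hi["qaly"], mid["cost"], mid["qaly"])
            if icer_lo > icer_hi:
                mid["dominance"] = EXTENDED
                convex.pop(i)
                changed = True
                break

    for r in rows:
        if r is base:
            r["inc_qaly_vs_comparator"] = math.nan
            r["icer_vs_comparator"] = math.nan
        else:
            r["inc_qaly_vs_comparator"] = r["qaly"] - base["qaly"]
            r["icer_vs_comparator"] = icer(r["cost"], r["qaly"],
                                           base["cost"], base["qaly"])
        r["frontier_icer"] = math.nan
    for prev, cur in zip(chain, chain[1:]):
        cur["frontier_icer"] = icer(cur["cost"], cur["qaly"],
                                    prev["cost"], prev["qaly"])

    df = pd.DataFrame(rows, columns=["strategy", "cost", "qaly",
                                     "inc_qaly_vs_comparator",
                                     "icer_vs_comparator", "dominance",
                                     "frontier_icer"])
    if wtp_threshold is not None:
        df["below_wtp_threshold"] = df["icer_vs_comparator"] < wtp_threshold
    return df


def render_table(df: pd.DataFrame, icer_decimals: int = 0) -> pd.DataFrame:
    """Presentation rounding: costs to 0.1, QALYs to 0.01, ICERs to the
    nearest unit (short-term style) or given decimals (long-term style)."""
    out = df.copy()
    out["cost"] = out["cost"].round(1)
    out["qaly"] = out["qaly"].round(2)
    out["inc_qaly_vs_comparator"] = out["inc_qaly_vs_comparator"].round(2)
    for col in ("icer_vs_comparator", "frontier_icer"):
        out[col] = out[col].round(icer_decimals)
    return out
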