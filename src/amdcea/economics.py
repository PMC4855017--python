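"""Incremental cost-effectiveness analysis across strategies.

ICERs are incremental cost over incremental QALYs between two strategies.
The efficiency frontier removes strictly dominated strategies (costlier and
no more effective than another) and extendedly dominated ones (removed
iteratively until ICERs increase moving up the frontier).  Net monetary
benefit linearizes the decision rule at a willingness-to-pay threshold;
verdict labels follow the WHO GDP-multiple convention (ICER vs usual care
at most 1x per-capita GDP: highly cost-effective; at most 3x:
cost-effective; above: not cost-effective).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from amdcea.engine import StrategyResult
from amdcea.states import Strategy

QALY_TOL = 1e-9

ON_FRONTIER = "on-frontier"
STRICTLY_DOMINATED = "strictly dominated"
EXTENDEDLY_DOMINATED = "extendedly dominated"


@dataclass(frozen=True)
class ICERResult:
    """An incremental comparison; ``value`` is $/QALY or NaN when flagged.

    ``flag`` is one of: "" (ordinary positive ICER), "dominant" (cheaper and
    more effective), "dominated" (costlier and less effective), or
    "no incremental effect" (QALY difference below tolerance).
    """

    value: float
    flag: str = ""

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def icer(a: StrategyResult, b: StrategyResult) -> ICERResult:
    """ICER of strategy ``b`` relative to ``a``: (cost_b - cost_a)/(QALY_b - QALY_a).

    Positive when b buys more QALYs at more cost.  A negative ratio is
    flagged: "dominant" when b is cheaper and more effective, "dominated"
    when b is costlier and less effective (the raw signed ratio is kept in
    ``value`` for reporting).
    """
    d_cost = b.cost - a.cost
    d_qaly = b.qalys - a.qalys
    if abs(d_qaly) < QALY_TOL:
        return ICERResult(value=float("nan"), flag="no incremental effect")
    value = d_cost / d_qaly
    if d_qaly > 0 and d_cost < 0:
        return ICERResult(value=value, flag="dominant")
    if d_qaly < 0 and d_cost > 0:
        return ICERResult(value=value, flag="dominated")
    return ICERResult(value=value)


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost, in $."""
    if wtp < 0:
        raise ValueError(f"willingness to pay must be >= 0 (got {wtp})")
    return wtp * result.qalys - result.cost


@dataclass
class FrontierRow:
    strategy: Strategy
    cost: float
    qalys: float
    vision_years: float
    status: str                    # on-frontier / strictly dominated / extendedly dominated
    icer_vs_next: float | None     # frontier ICER vs previous frontier strategy
    icer_vs_usual_care: float | None
    comment: str = ""


@dataclass
class CEFrontier:
    """Dominance-annotated strategy comparison (reference-case table shape)."""

    rows: list[FrontierRow]

    def row(self, strategy: Strategy) -> FrontierRow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(strategy)

    @property
    def frontier(self) -> list[FrontierRow]:
        """On-frontier rows in ascending cost order."""
        return sorted((r for r in self.rows if r.status == ON_FRONTIER),
                      key=lambda r: r.cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "strategy": r.strategy.value, "cost": r.cost, "vision_years": r.vision_years,
            "qalys": r.qalys, "icer_vs_usual_care": r.icer_vs_usual_care,
            "status": r.status, "comment": r.comment} for r in self.rows])


def _strictly_dominated(results: Sequence[StrategyResult]) -> set[int]:
    out = set()
    for i, a in enumerate(results):
        for j, b in enumerate(results):
            if i == j:
                continue
            # b dominates a: no costlier, no less effective, better on one.
            if (b.cost <= a.cost and b.qalys >= a.qalys
                    and (b.cost < a.cost or b.qalys > a.qalys)):
                out.add(i)
                break
    return out


def _extended_dominance(order: list[int],
                        results: Sequence[StrategyResult]) -> tuple[list[int], set[int]]:
    """Iteratively drop candidates until sequential ICERs strictly increase."""
    removed: set[int] = set()
    frontier = list(order)
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for pos in range(1, len(frontier) - 1):
            lo, mid, hi = (results[frontier[pos - 1]], results[frontier[pos]],
                           results[frontier[pos + 1]])
            icer_in = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_out = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_in >= icer_out - 1e-12:
                removed.add(frontier[pos])
                del frontier[pos]
                changed = True
                break
    return frontier, removed


def build_frontier(results: Iterable[StrategyResult],
                   gdp_per_capita: float | None = None) -> CEFrontier:
    """Classify strategies by dominance and attach frontier ICERs.

    ICER vs usual care is reported for every strategy (dominated ones
    included) whenever a usual-care arm is present.  With ``gdp_per_capita``
    given, a verdict comment is attached: "Dominated", "Highly
    cost-effective" (ICER vs usual care <= 1x GDP), "Cost-effective"
    (<= 3x GDP), or "Not cost-effective".
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("frontier needs at least two strategies")

    strict = _strictly_dominated(results)
    candidates = [i for i in range(len(results)) if i not in strict]
    # Sort by cost, tie-break on QALYs (equal-cost, lower-QALY already strict).
    candidates.sort(key=lambda i: (results[i].cost, results[i].qalys))
    frontier_idx, extended = _extended_dominance(candidates, results)

    usual = next((r for r in results if r.strategy == Strategy.USUAL_CARE), None)

    rows = []
    frontier_positions = {idx: pos for pos, idx in enumerate(frontier_idx)}
    for i, r in enumerate(results):
        if i in strict:
            status = STRICTLY_DOMINATED
        elif i in extended:
            status = EXTENDEDLY_DOMINATED
        else:
            status = ON_FRONTIER
        icer_next = None
        if status == ON_FRONTIER and frontier_positions[i] > 0:
            prev = results[frontier_idx[frontier_positions[i] - 1]]
            icer_next = icer(prev, r).value
        icer_uc = None
        if usual is not None and r.strategy != Strategy.USUAL_CARE:
            icer_uc = icer(usual, r).value
        comment = ""
        if gdp_per_capita is not None and r.strategy != Strategy.USUAL_CARE:
            if status != ON_FRONTIER:
                comment = "Dominated"
            elif icer_uc is not None and icer_uc <= gdp_per_capita:
                comment = "Highly cost-effective"
            elif icer_uc is not None and icer_uc <= 3 * gdp_per_capita:
                comment = "Cost-effective"
            else:
                comment = "Not cost-effective"
        rows.append(FrontierRow(strategy=r.strategy, cost=r.cost, qalys=r.qalys,
                                vision_years=r.vision_years, status=status,
                                icer_vs_next=icer_next, icer_vs_usual_care=icer_uc,
                                comment=comment))
    return CEFrontier(rows=rows)
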