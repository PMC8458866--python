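"""Incremental cost-effectiveness analysis: dominance, extended
dominance, frontier ICERs and net monetary benefit."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import StrategyOutcome

__all__ = [
    "FrontierResult",
    "compute_frontier",
    "net_monetary_benefit",
    "pairwise_icer",
]

FRONTIER = "frontier"
DOMINATED = "dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class FrontierResult:
    """Strategies ordered by cost with dominance labels and frontier ICERs."""

    table: pd.DataFrame  # strategy, cost, qaly, ly, status, icer

    @property
    def frontier(self) -> list[str]:
        t = self.table
        return list(t.loc[t["status"] == FRONTIER, "strategy"])

    @property
    def icers(self) -> dict[str, float]:
        """ICER vs the next cheaper frontier member, keyed by strategy."""
        t = self.table
        rows = t.loc[(t["status"] == FRONTIER) & t["icer"].notna()]
        return dict(zip(rows["strategy"], rows["icer"]))

    def status_of(self, name: str) -> str:
        row = self.table.loc[self.table["strategy"] == name]
        if row.empty:
            raise KeyError(name)
        return str(row["status"].iloc[0])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.2f")


def pairwise_icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """ICER of a versus b: incremental cost over incremental QALYs."""
    dq = a.mean_qaly - b.mean_qaly
    dc = a.mean_cost - b.mean_cost
    if dq == 0.0:
        return math_inf_signed(dc)
    return dc / dq


def math_inf_signed(dc: float) -> float:
    return float("inf") if dc >= 0 else float("-inf")


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """``wtp * QALY - cost``; the NMB-maximal strategy is frontier-optimal."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * outcome.mean_qaly - outcome.mean_cost


def compute_frontier(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Sort by cost, drop strongly and extendedly dominated strategies and
    report ICERs between consecutive frontier members.

    A strategy is strongly dominated when another costs no more and
    yields no fewer QALYs (strictly better in at least one); extendedly
    dominated when the ICER sequence along the cost-sorted nondominated
    set fails to increase.  Exact (cost, QALY) ties collapse to the
    lexically first name.
    """
    if not outcomes:
        raise ValueError("need at least one strategy")
    names = [o.strategy for o in outcomes]
    if len(set(names)) != len(names):
        raise ValueError("strategy names must be distinct")

    rows = sorted(outcomes, key=lambda o: (o.mean_cost, -o.mean_qaly, o.strategy))
    status: dict[str, str] = {}
    # exact ties: keep one deterministic representative
    kept: list[StrategyOutcome] = []
    for o in rows:
        if kept and kept[-1].mean_cost == o.mean_cost and kept[-1].mean_qaly == o.mean_qaly:
            status[o.strategy] = DOMINATED
            continue
        kept.append(o)
    # strong dominance: any cheaper-or-equal strategy with >= QALYs
    nondom: list[StrategyOutcome] = []
    best_q = -np.inf
    for o in kept:
        if o.mean_qaly <= best_q:
            status[o.strategy] = DOMINATED
        else:
            nondom.append(o)
            best_q = o.mean_qaly
    # extended dominance: enforce increasing ICERs along the frontier
    changed = True
    while changed and len(nondom) > 2:
        changed = False
        for i in range(1, len(nondom) - 1):
            lo, mid, hi = nondom[i - 1], nondom[i], nondom[i + 1]
            icer_lo = pairwise_icer(mid, lo)
            icer_hi = pairwise_icer(hi, mid)
            if icer_hi < icer_lo:
                status[mid.strategy] = EXTENDEDLY_DOMINATED
                del nondom[i]
                changed = True
                break
    for o in nondom:
        status[o.strategy] = FRONTIER

    frontier_names = {o.strategy for o in nondom}
    records = []
    prev: StrategyOutcome | None = None
    for o in rows:
        icer = np.nan
        if o.strategy in frontier_names:
            if prev is not None:
                icer = pairwise_icer(o, prev)
            prev = o
        records.append(
            {
                "strategy": o.strategy,
                "cost": o.mean_cost,
                "ly": o.mean_ly,
                "qaly": o.mean_qaly,
                "status": status[o.strategy],
                "icer": icer,
            }
        )
    return FrontierResult(table=pd.DataFrame.from_records(records))
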