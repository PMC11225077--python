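"""Incremental cost-effectiveness statistics.

ICERs, strict and extended dominance, the cost-effectiveness frontier
and net monetary benefit.  The frontier algorithm sorts arms by cost,
removes strictly dominated arms (no cheaper arm achieves at least the
same QALYs), then removes extendedly dominated arms until pairwise ICERs
increase monotonically along the frontier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import StrategyResult

__all__ = [
    "icer",
    "incremental_analysis",
    "net_monetary_benefit",
    "IncrementalRow",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
]

#: Flag values `icer` can return instead of a ratio.
DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def icer(delta_cost: float, delta_qalys: float):
    """Incremental cost-effectiveness ratio, or a dominance flag.

    Returns ``'dominant'`` (cheaper and more effective), ``'dominated'``
    (dearer and less effective), or ``'undefined'`` when the QALY
    difference is exactly zero; otherwise the ratio in USD/QALY.
    """
    if delta_qalys == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_qalys > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qalys < 0:
        return DOMINATED
    return delta_cost / delta_qalys


def net_monetary_benefit(cost: float, qalys: float, wtp: float):
    """NMB = wtp * qalys - cost (USD); higher is better at the threshold."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("wtp must be non-negative")
    return wtp * qalys - cost


@dataclass(frozen=True)
class IncrementalRow:
    strategy: str
    cost: float
    qalys: float
    delta_cost: float | None  # vs previous frontier arm; None off-frontier
    delta_qalys: float | None
    icer: float | str | None
    status: str  # dominant | dominated | extended-dominated | on-frontier


def _sorted_by_cost(results):
    # Deterministic tie-break: equal cost (then equal QALYs) keeps
    # alphabetical label order.
    return sorted(results, key=lambda r: (r.cost, -r.qalys, r.label))


def incremental_analysis(results: list[StrategyResult]) -> list[IncrementalRow]:
    """Frontier construction with strict and extended dominance.

    Returns one row per strategy sorted by cost.  Frontier rows carry the
    pairwise ICER versus the previous (cheaper) frontier arm; a frontier
    that collapses to a single arm marks that arm ``dominant``.
    The output is invariant to the input ordering.
    """
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least two strategies")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")

    ordered = _sorted_by_cost(results)
    status = {r.label: "on-frontier" for r in ordered}

    # Strict dominance: some arm at most as costly achieves >= QALYs
    # (with at least one strict inequality).
    for i, r in enumerate(ordered):
        for other in ordered:
            if other.label == r.label:
                continue
            if (
                other.cost <= r.cost
                and other.qalys >= r.qalys
                and (other.cost < r.cost or other.qalys > r.qalys)
            ):
                status[r.label] = "dominated"
                break

    # Extended dominance: remove arms until ICERs increase along the frontier.
    frontier = [r for r in ordered if status[r.label] == "on-frontier"]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_mid = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_hi = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_mid >= icer_hi:
                status[mid.label] = "extended-dominated"
                frontier.pop(i)
                changed = True
                break

    if len(frontier) == 1:
        status[frontier[0].label] = "dominant"

    frontier_labels = [r.label for r in frontier]
    rows = []
    for r in ordered:
        if r.label in frontier_labels:
            k = frontier_labels.index(r.label)
            if k == 0:
                rows.append(
                    IncrementalRow(r.label, r.cost, r.qalys, None, None, None,
                                   status[r.label])
                )
            else:
                prev = frontier[k - 1]
                dc, dq = r.cost - prev.cost, r.qalys - prev.qalys
                rows.append(
                    IncrementalRow(r.label, r.cost, r.qalys, dc, dq,
                                   icer(dc, dq), status[r.label])
                )
        else:
            rows.append(
                IncrementalRow(r.label, r.cost, r.qalys, None, None, None,
                               status[r.label])
            )
    return rows


def incremental_frame(rows: list[IncrementalRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in rows],
            "cost": [r.cost for r in rows],
            "qalys": [r.qalys for r in rows],
            "delta_cost": [r.delta_cost for r in rows],
            "delta_qalys": [r.delta_qalys for r in rows],
            "icer": [r.icer for r in rows],
            "status": [r.status for r in rows],
        }
    )
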