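"""Drug-cost scale calibration.

Pack prices read as one tablet per day imply annual medication costs in
the thousands of USD, while lifetime discounted totals for this model
are a few hundred USD — the two units cannot both be taken at face
value.  The ``calibrated`` cost model resolves this by scaling the
per-tablet-daily cost by a single factor, anchored so that a chosen
arm's total discounted lifetime cost equals a benchmark value (the base
case anchors the combination arm at its published 871 USD total).

Total cost is affine in the scale factor (occupancy does not depend on
costs), so the calibration is an exact two-run linear solve.
"""

from __future__ import annotations

from dataclasses import replace

from .parameters import ParameterSet
from .engine import run_cohort
from .strategies import build_strategy_set

__all__ = ["calibrate_drug_cost_scale", "with_drug_cost_scale"]


def with_drug_cost_scale(params: ParameterSet, scale: float) -> ParameterSet:
    """A copy of ``params`` with the calibrated drug-cost scale replaced."""
    return replace(params, settings=replace(params.settings, drug_cost_scale=scale))


def calibrate_drug_cost_scale(
    params: ParameterSet,
    target_cost: float,
    strategy_label: str = "polypill",
) -> float:
    """Scale factor making one arm's discounted lifetime cost hit a target.

    Solves the affine relation cost(scale) = cost(0) + scale * slope
    exactly from two deterministic runs.  A target below the arm's
    state-cost floor (drug cost cannot be negative) clamps the scale to
    zero.
    """
    if params.settings.cost_model != "calibrated":
        raise ValueError("calibration applies to the 'calibrated' cost model")
    strategies = {s.label: s for s in build_strategy_set(params)}
    if strategy_label not in strategies:
        raise ValueError(f"unknown strategy {strategy_label!r}")
    strat = strategies[strategy_label]

    cost0 = run_cohort(
        with_drug_cost_scale(params, 0.0), strat, collect_trace=False
    ).cost
    cost1 = run_cohort(
        with_drug_cost_scale(params, 1.0), strat, collect_trace=False
    ).cost
    slope = cost1 - cost0
    if slope <= 0:
        raise ValueError("drug cost has no effect on the chosen arm")
    return max((target_cost - cost0) / slope, 0.0)
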