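"""Markov cohort engine: transition matrices, propagation and rewards.

The cohort enters event-free at the start age and is propagated through
annual cycles to the maximum age.  Each cycle a person event-free faces
competing transitions to first stroke, heart failure, MI, angina or PVD
(baseline risk times the arm's relative effect, with incident stroke,
HF and MI split into an immediately fatal share and a nonfatal share),
plus background life-table mortality and an additional disease-specific
death hazard; the residual mass stays event-free.  Occupants of a
disease state face background mortality inflated by that disease's
standardized mortality ratio and otherwise remain (acute MI and angina
are one-cycle tunnels feeding their chronic post states).

Rewards: each cycle accrues cost (state cost plus annual medication cost
in every alive state) and utility-weighted life-years, discounted at
separate annual rates for costs and QALYs with start-of-cycle factors
``(1+r)**-t``.  Half-cycle correction (averaging start- and end-of-cycle
occupancy) is on by default and switchable off.

All probability arithmetic broadcasts over numpy arrays, so the same
code path serves the deterministic base case (scalars) and the
probabilistic sensitivity analysis (one vectorized run per strategy over
all Monte-Carlo draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import AgeRange, ParameterSet
from .states import (
    CHRONIC_STATES,
    EVENT_ENTRY_STATE,
    EVENTS,
    FATAL_EVENTS,
    HealthState,
    N_STATES,
    STATE_SMR_DISEASE,
    TUNNEL_SUCCESSOR,
)
from .strategies import Strategy, annual_medication_cost, build_strategy_set

__all__ = [
    "discount_factor",
    "interpolate_risk",
    "apply_relative_effect",
    "other_cause_mortality",
    "event_fatality",
    "build_transition_matrix",
    "run_cohort",
    "base_values",
    "CohortTrace",
    "StrategyResult",
]


def discount_factor(rate: float, cycle: int):
    """Present-value weight ``(1+rate)**-cycle`` for a given cycle."""
    if np.any(np.asarray(rate) < 0):
        raise ValueError("discount rate must be non-negative")
    if np.any(np.asarray(cycle) < 0):
        raise ValueError("cycle must be non-negative")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


def interpolate_risk(age, low, high, age_lo, age_hi):
    """Linear interpolation of a ranged input over the age span, clamped."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if np.any(low > high):
        raise ValueError("inverted range: low > high")
    if age_hi <= age_lo:
        raise ValueError("age_hi must exceed age_lo")
    frac = np.clip((age - age_lo) / (age_hi - age_lo), 0.0, 1.0)
    return low + frac * (high - low)


def apply_relative_effect(p, effect):
    """Apply a relative effect on the constant-rate scale: 1-(1-p)**e.

    Used for both risk ratios and hazard ratios; for small annual
    probabilities it coincides with multiplicative scaling, and it keeps
    the result a probability for any positive effect.
    """
    p = np.asarray(p, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if np.any(effect <= 0):
        raise ValueError("effect must be positive")
    if np.any((p >= 1.0) & (effect != 1.0)):
        raise ValueError("degenerate: p = 1 with a non-null effect")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must be a probability")
    return 1.0 - (1.0 - p) ** effect


def other_cause_mortality(lt: LifeTable, age: int, smr):
    """Background death probability at ``age`` under an SMR, capped at 1."""
    smr = np.asarray(smr, dtype=float)
    if np.any(smr <= 0):
        raise ValueError("smr must be positive")
    qx = lt.q(age)
    return np.minimum(1.0 - (1.0 - qx) ** smr, 1.0)


def event_fatality(
    event: str, age: int, sex: str, params: ParameterSet
):
    """Probability the incident event is immediately fatal.

    ``sex`` is 'male', 'female' or 'blend' (the settings male fraction);
    only MI fatality is sex- and age-dependent.
    """
    s = params.settings
    if event == "stroke":
        return params.mortality.fatal_stroke.mean
    if event == "hf":
        return params.mortality.fatal_hf.mean
    if event != "mi":
        raise ValueError(f"no case fatality defined for event {event!r}")

    def interp(sex_key: str) -> float:
        rng = params.mortality.fatal_mi[sex_key]
        return float(
            interpolate_risk(age, rng.low, rng.high, s.start_age, s.risk_span_end)
        )

    if sex in ("male", "female"):
        return interp(sex)
    if sex == "blend":
        mf = s.male_fraction
        return mf * interp("male") + (1.0 - mf) * interp("female")
    raise ValueError(f"unknown sex {sex!r}")


# ---------------------------------------------------------------------------
# Value maps: a flat name -> number (or draw array) view of the inputs.
# The same names serve the deterministic run (means), the tornado
# (perturbed means) and the PSA (arrays of draws).
# ---------------------------------------------------------------------------

def base_values(params: ParameterSet, strategies: list[Strategy] | None = None) -> dict:
    """Flat point-estimate value map for every model input."""
    if strategies is None:
        strategies = build_strategy_set(params)
    v: dict = {}
    for event, spec in params.baseline_risks.items():
        if isinstance(spec, AgeRange):
            v[f"risk.{event}.low"] = spec.low
            v[f"risk.{event}.high"] = spec.high
        else:
            v[f"risk.{event}"] = spec.mean
    for key, spec in params.utilities.items():
        v[f"util.{key}"] = spec.mean
    for key, spec in params.state_costs.items():
        v[f"cost.{key}"] = spec.mean
    v["fatal.stroke"] = params.mortality.fatal_stroke.mean
    v["fatal.hf"] = params.mortality.fatal_hf.mean
    for sex, rng in params.mortality.fatal_mi.items():
        v[f"fatal.mi.{sex}.low"] = rng.low
        v[f"fatal.mi.{sex}.high"] = rng.high
    for disease, spec in params.mortality.smr.items():
        v[f"smr.{disease}"] = spec.mean
    v["dd.p"] = params.mortality.disease_specific_death.mean
    for strat in strategies:
        v[f"price.{strat.label}"] = strat.price.mean
        for event in strat.specified_events():
            v[f"eff.{strat.label}.{event}"] = strat.effects[event].mean
    return v


def _effect(values: dict, label: str, event: str):
    return values.get(f"eff.{label}.{event}", 1.0)


def _risk_at_age(values: dict, event: str, age: int, settings):
    key = f"risk.{event}"
    if key in values:
        return np.asarray(values[key], dtype=float)
    return interpolate_risk(
        age,
        values[f"{key}.low"],
        values[f"{key}.high"],
        settings.start_age,
        settings.risk_span_end,
    )


def _fatal_mi_at_age(values: dict, age: int, settings):
    mf = settings.male_fraction
    male = interpolate_risk(
        age, values["fatal.mi.male.low"], values["fatal.mi.male.high"],
        settings.start_age, settings.risk_span_end,
    )
    female = interpolate_risk(
        age, values["fatal.mi.female.low"], values["fatal.mi.female.high"],
        settings.start_age, settings.risk_span_end,
    )
    return mf * male + (1.0 - mf) * female


def _composite_effect(values: dict, strategy: Strategy):
    """Geometric mean of the arm's studied event effects.

    Scales the disease-specific death hazard: an arm that lowers every
    event risk is assumed to lower cardiovascular background death
    commensurately.  Defaulted (never-studied) effects are excluded.
    """
    events = strategy.specified_events()
    if not events:
        return 1.0
    logs = [np.log(np.asarray(_effect(values, strategy.label, e), dtype=float))
            for e in events]
    return np.exp(sum(logs) / len(logs))


def _transition_matrix(
    values: dict, strategy: Strategy, age: int, qx: float, settings
) -> np.ndarray:
    """One-cycle transition matrix at ``age``; shape (..., 9, 9).

    Leading dimensions broadcast over any draw arrays present in
    ``values``.  Rows sum to one by residual-mass construction.
    """
    label = strategy.label
    fatal = {
        "stroke": np.asarray(values["fatal.stroke"], dtype=float),
        "hf": np.asarray(values["fatal.hf"], dtype=float),
        "mi": _fatal_mi_at_age(values, age, settings),
    }
    p_event = {}
    for event in EVENTS:
        base = _risk_at_age(values, event, age, settings)
        p_event[event] = apply_relative_effect(base, _effect(values, label, event))

    dd = apply_relative_effect(
        np.asarray(values["dd.p"], dtype=float), _composite_effect(values, strategy)
    )

    shape = np.broadcast_shapes(
        *(np.shape(x) for x in p_event.values()),
        np.shape(dd),
        *(np.shape(x) for x in fatal.values()),
    )
    m = np.zeros(shape + (N_STATES, N_STATES))

    ef = HealthState.EVENT_FREE
    dead = HealthState.DEAD
    death_mass = dd + qx
    exit_mass = dd + qx
    for event in EVENTS:
        p = p_event[event]
        if event in FATAL_EVENTS:
            f = fatal[event]
            m[..., ef, EVENT_ENTRY_STATE[event]] = p * (1.0 - f)
            death_mass = death_mass + p * f
        else:
            m[..., ef, EVENT_ENTRY_STATE[event]] = p
        exit_mass = exit_mass + p
    m[..., ef, dead] = death_mass
    stay = 1.0 - exit_mass
    if np.any(stay < -1e-12):
        raise ValueError(
            f"competing risks from EventFree exceed 1 at age {age} "
            f"(total {float(np.max(exit_mass)):.4f})"
        )
    m[..., ef, ef] = np.maximum(stay, 0.0)

    for state in CHRONIC_STATES:
        smr = np.asarray(values[f"smr.{STATE_SMR_DISEASE[state]}"], dtype=float)
        d = np.minimum(1.0 - (1.0 - qx) ** smr, 1.0)
        m[..., state, dead] = d
        m[..., state, state] = 1.0 - d
    for state, successor in TUNNEL_SUCCESSOR.items():
        smr = np.asarray(values[f"smr.{STATE_SMR_DISEASE[state]}"], dtype=float)
        d = np.minimum(1.0 - (1.0 - qx) ** smr, 1.0)
        m[..., state, dead] = d
        m[..., state, state] = 0.0
        m[..., state, successor] = 1.0 - d
    m[..., dead, dead] = 1.0
    return m


def build_transition_matrix(
    age: int,
    strategy: Strategy,
    params: ParameterSet,
    lt: LifeTable | None = None,
    values: dict | None = None,
) -> np.ndarray:
    """Public transition-matrix constructor (point estimates by default)."""
    lt = lt or params.life_table
    if values is None:
        values = base_values(params, [strategy])
    return _transition_matrix(values, strategy, age, lt.q(age), params.settings)


def max_event_free_exit(values: dict, strategy: Strategy, params: ParameterSet):
    """Max total exit probability from EventFree over all model ages.

    Used by the probabilistic analysis to identify draws whose competing
    risks are jointly infeasible (> 1) before running the engine.
    """
    s = params.settings
    lt = params.life_table
    worst = None
    for age in range(s.start_age, s.max_age):
        total = np.asarray(values["dd.p"], dtype=float) * 0.0
        total = total + apply_relative_effect(
            np.asarray(values["dd.p"], dtype=float),
            _composite_effect(values, strategy),
        )
        total = total + lt.q(age)
        for event in EVENTS:
            base = _risk_at_age(values, event, age, s)
            total = total + apply_relative_effect(
                base, _effect(values, strategy.label, event)
            )
        worst = total if worst is None else np.maximum(worst, total)
    return worst


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and reward accumulators for one strategy arm."""

    ages: np.ndarray  # (T,) age at the start of each cycle
    occupancy: np.ndarray  # (T+1, ..., 9) state fractions, cycle starts + final
    cycle_cost: np.ndarray  # (T, ...) undiscounted USD per person
    cycle_cost_disc: np.ndarray
    cycle_qaly: np.ndarray
    cycle_qaly_disc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        if self.occupancy.ndim != 2:
            raise ValueError("trace frames require a scalar (non-vectorized) run")
        df = pd.DataFrame(
            self.occupancy[:-1], columns=[s.name.lower() for s in HealthState]
        )
        df.insert(0, "age", self.ages)
        df["cycle_cost"] = self.cycle_cost
        df["cycle_cost_disc"] = self.cycle_cost_disc
        df["cycle_qaly"] = self.cycle_qaly
        df["cycle_qaly_disc"] = self.cycle_qaly_disc
        return df


@dataclass(frozen=True)
class StrategyResult:
    """Discounted per-person totals for one arm (plus the full trace)."""

    label: str
    cost: float | np.ndarray
    qalys: float | np.ndarray
    trace: CohortTrace | None = None


def _reward_vectors(values: dict, strategy: Strategy, settings):
    """(utility, cost) reward vectors over states; broadcast over draws."""
    drug = annual_medication_cost(
        np.asarray(values[f"price.{strategy.label}"], dtype=float),
        strategy.pack_size,
        strategy.tablets_per_day,
        settings.cost_model,
        settings.drug_cost_scale,
    )
    zeros = np.zeros(np.shape(drug))
    util = [
        np.asarray(values["util.event_free"], dtype=float) + zeros,
        np.asarray(values["util.stroke"], dtype=float) + zeros,
        np.asarray(values["util.hf"], dtype=float) + zeros,
        np.asarray(values["util.acute_mi"], dtype=float) + zeros,
        np.asarray(values["util.post_mi"], dtype=float) + zeros,
        np.asarray(values["util.acute_angina"], dtype=float) + zeros,
        np.asarray(values["util.post_angina"], dtype=float) + zeros,
        np.asarray(values["util.pvd"], dtype=float) + zeros,
        zeros,
    ]
    cost = [
        drug + zeros,
        np.asarray(values["cost.stroke"], dtype=float) + drug,
        np.asarray(values["cost.hf"], dtype=float) + drug,
        np.asarray(values["cost.acute_mi"], dtype=float) + drug,
        drug + zeros,
        np.asarray(values["cost.acute_angina"], dtype=float) + drug,
        drug + zeros,
        np.asarray(values["cost.pvd"], dtype=float) + drug,
        zeros,
    ]
    return np.stack(util, axis=-1), np.stack(cost, axis=-1)


def run_cohort(
    params: ParameterSet,
    strategy: Strategy,
    lt: LifeTable | None = None,
    values: dict | None = None,
    half_cycle: bool | None = None,
    collect_trace: bool = True,
) -> StrategyResult:
    """Propagate the cohort for one arm and accumulate discounted rewards.

    ``values`` overrides the point-estimate value map (used by the
    tornado and the PSA; draw arrays broadcast through the whole run).
    Totals are per person; the configured cohort size is a reporting
    multiplier only.
    """
    s = params.settings
    lt = lt or params.life_table
    if values is None:
        values = base_values(params, [strategy])
    hcc = s.half_cycle_correction if half_cycle is None else half_cycle

    util_vec, cost_vec = _reward_vectors(values, strategy, s)
    lead_shape = util_vec.shape[:-1]
    ages = np.arange(s.start_age, s.max_age)
    T = ages.size

    x = np.zeros(lead_shape + (N_STATES,))
    x[..., HealthState.EVENT_FREE] = 1.0

    occ = np.empty((T + 1,) + x.shape) if collect_trace else None
    if collect_trace:
        occ[0] = x
    cost_cycles = np.empty((T,) + lead_shape)
    cost_cycles_disc = np.empty_like(cost_cycles)
    qaly_cycles = np.empty_like(cost_cycles)
    qaly_cycles_disc = np.empty_like(cost_cycles)

    total_cost = np.zeros(lead_shape)
    total_qaly = np.zeros(lead_shape)
    for t, age in enumerate(ages):
        m = _transition_matrix(values, strategy, int(age), lt.q(int(age)), s)
        x_next = np.einsum("...i,...ij->...j", x, m)
        x_reward = 0.5 * (x + x_next) if hcc else x
        c = np.sum(x_reward * cost_vec, axis=-1)
        q = np.sum(x_reward * util_vec, axis=-1)
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(q))):
            raise ValueError(f"non-finite occupancy or reward at age {age}")
        dc = discount_factor(s.discount_cost, t)
        dq = discount_factor(s.discount_qaly, t)
        cost_cycles[t], cost_cycles_disc[t] = c, c * dc
        qaly_cycles[t], qaly_cycles_disc[t] = q, q * dq
        total_cost = total_cost + c * dc
        total_qaly = total_qaly + q * dq
        x = x_next
        if collect_trace:
            occ[t + 1] = x

    trace = None
    if collect_trace:
        trace = CohortTrace(
            ages=ages,
            occupancy=occ,
            cycle_cost=cost_cycles,
            cycle_cost_disc=cost_cycles_disc,
            cycle_qaly=qaly_cycles,
            cycle_qaly_disc=qaly_cycles_disc,
        )
    squeeze = (lambda a: float(a) if a.shape == () else a)
    return StrategyResult(
        label=strategy.label,
        cost=squeeze(total_cost),
        qalys=squeeze(total_qaly),
        trace=trace,
    )


def run_all_strategies(
    params: ParameterSet,
    strategies: list[Strategy] | None = None,
    values: dict | None = None,
    collect_trace: bool = True,
) -> list[StrategyResult]:
    """Run every arm under one shared value map."""
    if strategies is None:
        strategies = build_strategy_set(params)
    if values is None:
        values = base_values(params, strategies)
    return [
        run_cohort(params, strat, values=values, collect_trace=collect_trace)
        for strat in strategies
    ]
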