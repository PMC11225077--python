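"""Sensitivity analyses: one-way tornado, Monte-Carlo PSA, CEAC.

The tornado varies each scalar input (and each age-ranged input as a
unit) by a symmetric relative amount around its mean, holding everything
else fixed, and ranks inputs by the spread they induce on the chosen
incremental outcome.

The PSA draws every uncertain input jointly and independently from its
fitted distribution — one draw vector shared by all strategy arms within
an iteration — and reruns the full cohort model per arm.  Age-ranged
inputs are drawn comonotonically (one uniform quantile drives both
endpoint distributions) so the sampled range stays ordered.  Draws whose
competing risks jointly exceed probability one in some cycle are
resampled (bounded retries, counted).

The cost-effectiveness acceptability curve reports, per willingness-to-
pay value, the fraction of iterations in which each arm attains maximal
net monetary benefit (exact ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cea import net_monetary_benefit
from .distributions import (
    DistributionSpec,
    beta_from_moments,
    rng_stream,
    sample_parameter,
)
from .engine import base_values, max_event_free_exit, run_cohort
from .parameters import AgeRange, ParameterSet
from .strategies import Strategy, build_strategy_set

__all__ = [
    "TornadoBar",
    "tornado",
    "tornado_frame",
    "PSAResult",
    "run_psa",
    "ceac",
    "quadrant_summary",
    "default_wtp_grid",
]

MAX_PSA_RETRIES = 100


# ---------------------------------------------------------------------------
# Tornado
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoBar:
    parameter: str
    low: float  # outcome with the parameter at mean*(1-delta)
    high: float  # outcome with the parameter at mean*(1+delta)

    @property
    def spread(self) -> float:
        return self.high - self.low


def _clamp_probability(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def _tornado_groups(params: ParameterSet, arms: tuple[str, str]) -> dict:
    """name -> (keys, clamp) for every input entering the compared arms."""
    groups: dict = {}

    def add(name, keys, clamp=None):
        groups[name] = (keys, clamp)

    for event, spec in params.baseline_risks.items():
        if isinstance(spec, AgeRange):
            add(f"risk.{event}", [f"risk.{event}.low", f"risk.{event}.high"],
                _clamp_probability)
        else:
            add(f"risk.{event}", [f"risk.{event}"], _clamp_probability)
    for key, spec in params.utilities.items():
        if not spec.is_fixed:
            add(f"util.{key}", [f"util.{key}"], _clamp_probability)
    for key in params.state_costs:
        add(f"cost.{key}", [f"cost.{key}"])
    add("fatal.stroke", ["fatal.stroke"], _clamp_probability)
    add("fatal.hf", ["fatal.hf"], _clamp_probability)
    add(
        "fatal.mi",
        [f"fatal.mi.{sex}.{end}" for sex in ("male", "female")
         for end in ("low", "high")],
        _clamp_probability,
    )
    for disease in params.mortality.smr:
        add(f"smr.{disease}", [f"smr.{disease}"])
    add("dd.p", ["dd.p"], _clamp_probability)
    for label in arms:
        add(f"price.{label}", [f"price.{label}"])
    return groups


def tornado(
    params: ParameterSet,
    comparison: tuple[str, str] = ("polypill", "enalapril"),
    delta: float = 0.2,
    outcome: str = "nmb",
    wtp: float | None = None,
    parameters: list[str] | None = None,
    symmetric: bool = True,
) -> list[TornadoBar]:
    """One-way sensitivity bars on an incremental outcome.

    ``outcome='nmb'``: incremental net monetary benefit of the first arm
    versus the second at ``wtp`` (default: the configured threshold).
    ``outcome='icer'``: the pairwise ICER.  With ``symmetric=False`` the
    low side is the base case (a one-sided, increase-only tornado).
    Bars come back sorted by absolute spread, largest first.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if outcome not in ("nmb", "icer"):
        raise ValueError("outcome must be 'nmb' or 'icer'")
    wtp = params.settings.wtp if wtp is None else wtp

    strategies = {s.label: s for s in build_strategy_set(params)}
    try:
        arm_a, arm_b = (strategies[label] for label in comparison)
    except KeyError as exc:
        raise ValueError(f"unknown strategy in comparison: {exc}") from exc

    base = base_values(params, list(strategies.values()))
    # per-arm effect entries join the perturbable set
    groups = _tornado_groups(params, comparison)
    for strat in (arm_a, arm_b):
        for event in strat.specified_events():
            key = f"eff.{strat.label}.{event}"
            groups.setdefault(key, ([key], None))

    if parameters is not None:
        unknown = set(parameters) - set(groups)
        if unknown:
            raise ValueError(f"unknown tornado parameters: {sorted(unknown)}")
        groups = {k: groups[k] for k in parameters}
    if not groups:
        raise ValueError("empty tornado parameter list")

    def evaluate(values: dict) -> float:
        ra = run_cohort(params, arm_a, values=values, collect_trace=False)
        rb = run_cohort(params, arm_b, values=values, collect_trace=False)
        if outcome == "nmb":
            return net_monetary_benefit(ra.cost, ra.qalys, wtp) - \
                net_monetary_benefit(rb.cost, rb.qalys, wtp)
        dq = ra.qalys - rb.qalys
        return (ra.cost - rb.cost) / dq if dq != 0 else float("nan")

    def perturbed(keys, clamp, factor):
        values = dict(base)
        for key in keys:
            new = base[key] * factor
            values[key] = clamp(new) if clamp else new
        return values

    base_outcome = evaluate(base)
    bars = []
    for name, (keys, clamp) in groups.items():
        lo = (
            evaluate(perturbed(keys, clamp, 1.0 - delta))
            if symmetric
            else base_outcome
        )
        hi = evaluate(perturbed(keys, clamp, 1.0 + delta))
        bars.append(TornadoBar(parameter=name, low=lo, high=hi))
    bars.sort(key=lambda b: abs(b.spread), reverse=True)
    return bars


def tornado_frame(bars: list[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [b.parameter for b in bars],
            "low": [b.low for b in bars],
            "high": [b.high for b in bars],
            "spread": [b.spread for b in bars],
        }
    )


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

def _beta_ppf(u, spec: DistributionSpec):
    if spec.is_fixed:
        return np.full(np.shape(u), spec.mean)
    p = beta_from_moments(spec.mean, spec.sd)
    return stats.beta.ppf(u, p.alpha, p.beta)


def _draw_range(rng_pair: AgeRange, u):
    lo_spec, hi_spec = rng_pair.endpoint_specs()
    lo = _beta_ppf(u, lo_spec)
    hi = _beta_ppf(u, hi_spec)
    return np.minimum(lo, hi), np.maximum(lo, hi)


def draw_values(
    params: ParameterSet,
    strategies: list[Strategy],
    n: int,
    rng: np.random.Generator,
) -> dict:
    """One joint, independent draw vector of length ``n`` per input."""
    conv = params.settings.lognormal_convention
    v: dict = {}
    for event, spec in params.baseline_risks.items():
        if isinstance(spec, AgeRange):
            u = rng.uniform(size=n)
            v[f"risk.{event}.low"], v[f"risk.{event}.high"] = _draw_range(spec, u)
        else:
            v[f"risk.{event}"] = sample_parameter(spec, rng, n, conv)
    for key, spec in params.utilities.items():
        v[f"util.{key}"] = sample_parameter(spec, rng, n, conv)
    for key, spec in params.state_costs.items():
        v[f"cost.{key}"] = sample_parameter(spec, rng, n, conv)
    v["fatal.stroke"] = sample_parameter(params.mortality.fatal_stroke, rng, n, conv)
    v["fatal.hf"] = sample_parameter(params.mortality.fatal_hf, rng, n, conv)
    for sex, rng_pair in params.mortality.fatal_mi.items():
        u = rng.uniform(size=n)
        lo, hi = _draw_range(rng_pair, u)
        v[f"fatal.mi.{sex}.low"], v[f"fatal.mi.{sex}.high"] = lo, hi
    for disease, spec in params.mortality.smr.items():
        v[f"smr.{disease}"] = sample_parameter(spec, rng, n, conv)
    v["dd.p"] = sample_parameter(
        params.mortality.disease_specific_death, rng, n, conv
    )
    for strat in strategies:
        v[f"price.{strat.label}"] = sample_parameter(strat.price, rng, n, conv)
        for event in strat.specified_events():
            v[f"eff.{strat.label}.{event}"] = sample_parameter(
                strat.effects[event], rng, n, conv
            )
    return v


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo samples: shared parameter draws plus per-arm totals."""

    n: int
    seed: int
    labels: list[str]
    costs: np.ndarray  # (n, n_strategies)
    qalys: np.ndarray  # (n, n_strategies)
    values: dict  # parameter name -> (n,) draw array
    n_resampled: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long format: iteration, strategy, cost, qalys."""
        frames = []
        for j, label in enumerate(self.labels):
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n),
                        "strategy": label,
                        "cost": self.costs[:, j],
                        "qalys": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def parameter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: np.asarray(val) for k, val in self.values.items()})


def run_psa(
    params: ParameterSet,
    n: int,
    seed: int,
    strategies: list[Strategy] | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` joint draws.

    Reproducible: the same (params, n, seed) always returns identical
    samples.  Iterations whose drawn competing risks are infeasible in
    any arm are resampled (at most ``MAX_PSA_RETRIES`` rounds).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if strategies is None:
        strategies = build_strategy_set(params)
    rng = rng_stream(seed, "psa")

    values = draw_values(params, strategies, n, rng)
    n_resampled = 0
    for _ in range(MAX_PSA_RETRIES):
        excess = np.zeros(n)
        for strat in strategies:
            excess = np.maximum(
                excess, np.asarray(max_event_free_exit(values, strat, params))
            )
        bad = excess > 1.0
        if not np.any(bad):
            break
        n_bad = int(bad.sum())
        n_resampled += n_bad
        fresh = draw_values(params, strategies, n_bad, rng)
        for key in values:
            arr = np.array(values[key], dtype=float)
            arr[bad] = fresh[key]
            values[key] = arr
    else:
        raise RuntimeError(
            f"PSA still infeasible after {MAX_PSA_RETRIES} resampling rounds"
        )

    costs = np.empty((n, len(strategies)))
    qalys = np.empty((n, len(strategies)))
    for j, strat in enumerate(strategies):
        res = run_cohort(params, strat, values=values, collect_trace=False)
        costs[:, j] = res.cost
        qalys[:, j] = res.qalys
    return PSAResult(
        n=n,
        seed=seed,
        labels=[s.label for s in strategies],
        costs=costs,
        qalys=qalys,
        values=values,
        n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------
# CEAC and cost-effectiveness plane
# ---------------------------------------------------------------------------

def default_wtp_grid(wtp: float = 21768.0, top: float = 60000.0, step: float = 2000.0):
    """Regular WTP grid guaranteed to contain the decision threshold."""
    grid = set(np.arange(0.0, top + step, step).tolist())
    grid.add(float(wtp))
    return sorted(grid)


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Probability each arm is optimal (max NMB) at each WTP value.

    Exact NMB ties within an iteration split the win equally, so the
    probabilities sum to one across arms at every threshold.
    """
    wtp_grid = list(wtp_grid)
    if psa.n == 0 or not wtp_grid:
        raise ValueError("ceac needs non-empty PSA samples and WTP grid")
    rows = []
    for wtp in wtp_grid:
        nmb = net_monetary_benefit(psa.costs, psa.qalys, wtp)
        best = nmb.max(axis=1, keepdims=True)
        wins = (nmb == best).astype(float)
        wins /= wins.sum(axis=1, keepdims=True)
        probs = wins.mean(axis=0)
        for label, p in zip(psa.labels, probs):
            rows.append({"wtp": wtp, "strategy": label, "probability": p})
    return pd.DataFrame(rows)


def quadrant_summary(psa: PSAResult, reference: str = "polypill") -> pd.DataFrame:
    """Cost-effectiveness-plane quadrant fractions vs each comparator.

    Incremental QALYs and costs of the reference arm against every other
    arm; 'southeast' is more effective at lower (or equal) cost.
    Fractions sum to one per comparator.
    """
    if reference not in psa.labels:
        raise ValueError(f"reference strategy {reference!r} not in PSA")
    ref = psa.labels.index(reference)
    rows = []
    for j, label in enumerate(psa.labels):
        if label == reference:
            continue
        dq = psa.qalys[:, ref] - psa.qalys[:, j]
        dc = psa.costs[:, ref] - psa.costs[:, j]
        rows.append(
            {
                "comparator": label,
                "northeast": float(np.mean((dq >= 0) & (dc > 0))),
                "southeast": float(np.mean((dq >= 0) & (dc <= 0))),
                "southwest": float(np.mean((dq < 0) & (dc <= 0))),
                "northwest": float(np.mean((dq < 0) & (dc > 0))),
            }
        )
    return pd.DataFrame(rows)
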