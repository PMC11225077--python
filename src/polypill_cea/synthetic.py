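"""Synthetic stand-ins for inputs the analysis needs but no source prints.

Two such inputs exist: a national life table (only summary mortality is
ever published alongside decision models of this kind) and the age shape
of the event risks, which are published only as ranges over the adult age
span.  The life table stand-in is a Gompertz hazard — log-linear in age,
the standard demographic description of adult mortality — calibrated so
that remaining life expectancy at the cohort entry age matches a stated
target (default 42 years at age 35, plausible for Iran circa 2020).  It
is a stand-in, not a national statistic: absolute cost and QALY totals
shift with it, while incremental comparisons between arms are far less
sensitive.

Event-risk ranges are expanded linearly over the age span; the true age
pattern (Framingham-shaped risk) is unavailable, and the linear profile
is the documented modelling stance shared with the engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .lifetable import LifeTable

__all__ = [
    "GompertzSpec",
    "generate_life_table",
    "calibrate_gompertz",
    "generate_risk_profiles",
    "make_fixture_config",
    "base_config_dict",
]

_LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz adult mortality: h(age) = h0 * 2**((age - start_age)/doubling).

    ``hazard_at_start`` is the annual mortality hazard at ``start_age``;
    ``doubling_years`` is the age interval over which the hazard doubles
    (the Gompertz slope is ln 2 / doubling_years).  ``q`` at the terminal
    age is forced to 1 so the model horizon closes.
    """

    hazard_at_start: float
    doubling_years: float
    start_age: int = 35
    terminal_age: int = 100

    def __post_init__(self) -> None:
        if self.hazard_at_start <= 0:
            raise ValueError("hazard_at_start must be positive")
        if self.doubling_years <= 0:
            raise ValueError(
                "doubling_years must be positive (hazard must increase with age)"
            )
        if self.terminal_age <= self.start_age:
            raise ValueError("terminal_age must exceed start_age")

    def hazard(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.hazard_at_start * 2.0 ** ((age - self.start_age) / self.doubling_years)


def generate_life_table(spec: GompertzSpec) -> LifeTable:
    """Deterministic life table from a Gompertz spec.

    ``qx = 1 - exp(-h(age))`` at each one-year age; monotone in age, with
    the terminal entry forced to 1.
    """
    ages = np.arange(spec.start_age, spec.terminal_age + 1)
    qx = 1.0 - np.exp(-spec.hazard(ages))
    qx = np.minimum(qx, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def calibrate_gompertz(
    target_life_expectancy: float = 42.0,
    doubling_years: float = 8.0,
    start_age: int = 35,
    terminal_age: int = 100,
) -> GompertzSpec:
    """Solve the baseline hazard so that LE at ``start_age`` hits a target.

    One-dimensional and monotone (a larger baseline hazard always lowers
    life expectancy), so a bracketing root-find is exact and deterministic.
    """

    def le_minus_target(h0: float) -> float:
        spec = GompertzSpec(h0, doubling_years, start_age, terminal_age)
        lt = generate_life_table(spec)
        return lt.life_expectancy(start_age) - target_life_expectancy

    h0 = brentq(le_minus_target, 1e-6, 0.2, xtol=1e-12)
    return GompertzSpec(float(h0), doubling_years, start_age, terminal_age)


def generate_risk_profiles(params) -> pd.DataFrame:
    """Per-age annual event risks implied by a parameter set.

    Stroke and heart failure are constant; MI, angina and PVD risks are
    expanded linearly between their published range endpoints over
    [start_age, max_age].  Returns a DataFrame with one row per age and
    one column per event.
    """
    from .engine import interpolate_risk  # local import avoids a cycle

    s = params.settings
    ages = np.arange(s.start_age, s.max_age + 1)
    out = {"age": ages}
    for event, spec in params.baseline_risks.items():
        if hasattr(spec, "low"):
            out[event] = np.array(
                [
                    interpolate_risk(
                        a, spec.low, spec.high, s.start_age, s.risk_span_end
                    )
                    for a in ages
                ]
            )
        else:
            out[event] = np.full(ages.shape, spec.mean)
    return pd.DataFrame(out)


def base_config_dict() -> dict:
    """The shipped base-case configuration as a plain dict."""
    text = resources.files("polypill_cea").joinpath("data/base_case.yaml").read_text()
    return yaml.safe_load(text)


_JITTERABLE_SECTIONS = ("baseline_risks", "utilities", "state_costs", "effects")


def _jitter_means(node, rng, rel):
    """Recursively perturb `mean`/`low`/`high` entries by +-rel (uniform)."""
    if isinstance(node, dict):
        if node.get("dist") == "fixed":
            return  # point-mass inputs (e.g. the event-free utility) stay put
        for key, val in node.items():
            if key in ("mean", "low", "high") and isinstance(val, (int, float)):
                factor = 1.0 + rel * float(rng.uniform(-1.0, 1.0))
                new = float(val) * factor
                if node.get("dist", "beta") == "beta" or key in ("low", "high"):
                    new = min(new, 0.999)
                node[key] = round(new, 10)
            else:
                _jitter_means(val, rng, rel)


def make_fixture_config(
    path, seed: int = 0, jitter: float = 0.0, life_table_csv=None
) -> Path:
    """Write a complete, loadable model configuration.

    With ``jitter=0`` the output is the byte-identical base case whatever
    the seed.  A positive ``jitter`` perturbs distribution means by up to
    that relative amount (seeded), for stress-test fixtures; perturbed
    configs still satisfy every load-time validation.  If
    ``life_table_csv`` is given, the generated Gompertz life table is also
    written there and the config points at it instead of embedding the
    Gompertz spec.
    """
    cfg = base_config_dict()
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        for section in _JITTERABLE_SECTIONS:
            _jitter_means(cfg[section], rng, jitter)
    if life_table_csv is not None:
        lt_cfg = cfg["life_table"]
        spec = calibrate_gompertz(
            target_life_expectancy=lt_cfg["target_life_expectancy"],
            doubling_years=lt_cfg["doubling_years"],
            start_age=cfg["settings"]["start_age"],
            terminal_age=lt_cfg["terminal_age"],
        )
        generate_life_table(spec).to_csv(life_table_csv)
        lt_path = Path(life_table_csv)
        if lt_path.resolve().parent == Path(path).resolve().parent:
            lt_ref = lt_path.name  # keep the fixture directory relocatable
        else:
            lt_ref = str(lt_path.resolve())
        cfg["life_table"] = {"kind": "csv", "path": lt_ref}
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
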