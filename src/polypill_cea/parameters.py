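"""Model parameter bundle: loading, validation and serialization.

The full input set of the evaluation — baseline event risks, state
utilities, state costs, drug pack prices, per-arm relative effects and
the mortality block — lives in a flat, human-editable YAML configuration.
``load_parameters`` parses and validates it into a :class:`ParameterSet`;
every probability is checked against [0, 1], ranged inputs against
``low <= high``, and each (mean, sd) pair against the feasibility of its
declared distribution family.  Validation failures name the offending
field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .distributions import DistributionSpec
from .lifetable import LifeTable
from .states import EVENTS

__all__ = ["AgeRange", "Settings", "MortalityBlock", "ParameterSet", "load_parameters"]

log = logging.getLogger("polypill_cea")

COST_MODELS = ("per_tablet_daily", "per_pack_monthly", "calibrated")
STRATEGY_LABELS = (
    "polypill",
    "atorvastatin",
    "hydrochlorothiazide",
    "aspirin",
    "enalapril",
    "valsartan",
)


class ValidationError(ValueError):
    """A named, load-time configuration failure."""


@dataclass(frozen=True)
class AgeRange:
    """An input published as a [low, high] range over the adult age span.

    Interpreted as varying linearly with age between the cohort start age
    and the model's maximum age.  Each endpoint carries its own SD so the
    range can be sampled in the probabilistic analysis.
    """

    low: float
    high: float
    sd_low: float = 0.0
    sd_high: float = 0.0
    family: str = "beta"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"inverted range: low {self.low} > high {self.high}")

    def endpoint_specs(self) -> tuple[DistributionSpec, DistributionSpec]:
        fam_lo = self.family if self.sd_low > 0 else "fixed"
        fam_hi = self.family if self.sd_high > 0 else "fixed"
        return (
            DistributionSpec(fam_lo, self.low, self.sd_low),
            DistributionSpec(fam_hi, self.high, self.sd_high),
        )


@dataclass(frozen=True)
class Settings:
    start_age: int = 35
    max_age: int = 100
    discount_cost: float = 0.058
    discount_qaly: float = 0.03
    wtp: float = 21768.0
    cohort_size: int = 10000
    half_cycle_correction: bool = True
    lognormal_convention: str = "arithmetic"
    cost_model: str = "calibrated"
    drug_cost_scale: float = 1.0
    polypill_variant: str = "V"
    male_fraction: float = 0.5
    #: Age at which ranged inputs reach their upper endpoint (risks and MI
    #: case fatality are clamped there for older ages).
    risk_span_end: int = 85

    def __post_init__(self) -> None:
        if self.max_age <= self.start_age:
            raise ValidationError("settings.max_age must exceed settings.start_age")
        for name in ("discount_cost", "discount_qaly"):
            if getattr(self, name) < 0:
                raise ValidationError(f"settings.{name} must be non-negative")
        if self.cost_model not in COST_MODELS:
            raise ValidationError(
                f"settings.cost_model must be one of {COST_MODELS}"
            )
        if self.polypill_variant not in ("E", "V"):
            raise ValidationError("settings.polypill_variant must be 'E' or 'V'")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValidationError("settings.male_fraction must lie in [0, 1]")
        if self.drug_cost_scale < 0:
            raise ValidationError("settings.drug_cost_scale must be non-negative")
        if not self.start_age < self.risk_span_end <= self.max_age:
            raise ValidationError(
                "settings.risk_span_end must lie in (start_age, max_age]"
            )


@dataclass(frozen=True)
class MortalityBlock:
    fatal_stroke: DistributionSpec
    fatal_hf: DistributionSpec
    fatal_mi: dict  # sex -> AgeRange
    smr: dict  # disease -> DistributionSpec
    disease_specific_death: DistributionSpec


@dataclass(frozen=True)
class ParameterSet:
    settings: Settings
    life_table: LifeTable
    baseline_risks: dict  # event -> DistributionSpec | AgeRange
    utilities: dict  # state key -> DistributionSpec
    state_costs: dict  # state key -> DistributionSpec
    drug_prices: dict  # drug -> dose -> DistributionSpec
    effects: dict  # strategy -> event -> DistributionSpec
    mortality: MortalityBlock
    cost_components: dict = field(default_factory=dict)
    life_table_config: dict = field(default_factory=dict)

    def effect_spec(self, strategy: str, event: str) -> DistributionSpec:
        """The relative effect of ``strategy`` on ``event``.

        Pairs absent from the configuration (printed as a dash in the
        source tables) default to a fixed null effect of 1.0.
        """
        spec = self.effects.get(strategy, {}).get(event)
        if spec is None:
            log.info("effect (%s, %s) not specified; defaulting to 1.0", strategy, event)
            return DistributionSpec("fixed", 1.0, 0.0)
        return spec

    def capped_parameters(self) -> list[str]:
        """Names of inputs whose Beta SD had to be capped for sampling."""
        capped = []
        for section, entries in (
            ("utilities", self.utilities),
            ("state_costs", self.state_costs),
            ("baseline_risks", self.baseline_risks),
        ):
            for key, spec in entries.items():
                if isinstance(spec, AgeRange):
                    lo, hi = spec.endpoint_specs()
                    if lo.sd_capped:
                        capped.append(f"{section}.{key}.low")
                    if hi.sd_capped:
                        capped.append(f"{section}.{key}.high")
                elif spec.sd_capped:
                    capped.append(f"{section}.{key}")
        for name, spec in (
            ("mortality.fatal_stroke", self.mortality.fatal_stroke),
            ("mortality.fatal_hf", self.mortality.fatal_hf),
            ("mortality.disease_specific_death", self.mortality.disease_specific_death),
        ):
            if spec.sd_capped:
                capped.append(name)
        for sex, rng in self.mortality.fatal_mi.items():
            lo, hi = rng.endpoint_specs()
            if lo.sd_capped:
                capped.append(f"mortality.fatal_mi.{sex}.low")
            if hi.sd_capped:
                capped.append(f"mortality.fatal_mi.{sex}.high")
        return capped

    def defaulted_effects(self) -> list[str]:
        """(strategy, event) pairs that fall back to the null effect."""
        out = []
        for label in STRATEGY_LABELS:
            source = "enalapril" if label == "valsartan" else label
            for event in EVENTS:
                if event not in self.effects.get(source, {}):
                    out.append(f"{label}.{event}")
        return out

    def validation_report(self) -> str:
        """Plain-text audit of every divergence from the printed inputs."""
        lines = ["# parameter validation report"]
        capped = self.capped_parameters()
        lines.append(f"beta SDs capped at sampling time: {len(capped)}")
        lines.extend(f"  - {name}" for name in capped)
        defaulted = self.defaulted_effects()
        lines.append(f"effects defaulted to 1.0 (printed as a dash): {len(defaulted)}")
        lines.extend(f"  - {name}" for name in defaulted)
        gamma_smrs = [k for k, v in self.mortality.smr.items() if v.family == "gamma"]
        if gamma_smrs:
            lines.append(
                "SMRs carried as Gamma (means above 1 are outside the Beta support): "
                + ", ".join(sorted(gamma_smrs))
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        def spec_dict(spec):
            d = {"mean": spec.mean, "sd": spec.sd, "dist": spec.family}
            if spec.kind:
                d["kind"] = spec.kind
            return d

        def range_dict(rng):
            return {
                "low": rng.low,
                "high": rng.high,
                "sd_low": rng.sd_low,
                "sd_high": rng.sd_high,
                "dist": rng.family,
            }

        s = self.settings
        return {
            "settings": {
                "start_age": s.start_age,
                "max_age": s.max_age,
                "discount_cost": s.discount_cost,
                "discount_qaly": s.discount_qaly,
                "wtp": s.wtp,
                "cohort_size": s.cohort_size,
                "half_cycle_correction": s.half_cycle_correction,
                "lognormal_convention": s.lognormal_convention,
                "cost_model": s.cost_model,
                "drug_cost_scale": s.drug_cost_scale,
                "polypill_variant": s.polypill_variant,
                "male_fraction": s.male_fraction,
                "risk_span_end": s.risk_span_end,
            },
            "life_table": dict(self.life_table_config),
            "baseline_risks": {
                k: (range_dict(v) if isinstance(v, AgeRange) else spec_dict(v))
                for k, v in self.baseline_risks.items()
            },
            "utilities": {k: spec_dict(v) for k, v in self.utilities.items()},
            "state_costs": {k: spec_dict(v) for k, v in self.state_costs.items()},
            "cost_components": self.cost_components,
            "drug_prices": {
                drug: {dose: spec_dict(v) for dose, v in doses.items()}
                for drug, doses in self.drug_prices.items()
            },
            "effects": {
                strat: {ev: spec_dict(v) for ev, v in evs.items()}
                for strat, evs in self.effects.items()
            },
            "mortality": {
                "fatal_stroke": spec_dict(self.mortality.fatal_stroke),
                "fatal_hf": spec_dict(self.mortality.fatal_hf),
                "fatal_mi": {
                    sex: range_dict(v) for sex, v in self.mortality.fatal_mi.items()
                },
                "smr": {k: spec_dict(v) for k, v in self.mortality.smr.items()},
                "disease_specific_death": spec_dict(
                    self.mortality.disease_specific_death
                ),
            },
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _require(mapping: dict, key: str, where: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ValidationError(f"missing required field {where}.{key}")
    return mapping[key]


def _parse_spec(node: dict, name: str, probability: bool = False) -> DistributionSpec:
    mean = float(_require(node, "mean", name))
    sd = float(node.get("sd", 0.0))
    family = node.get("dist", "beta")
    if sd == 0.0:
        family = "fixed"
    if probability and not 0.0 <= mean <= 1.0:
        raise ValidationError(f"{name}.mean = {mean} outside [0, 1]")
    try:
        return DistributionSpec(family, mean, sd, kind=node.get("kind"))
    except ValueError as exc:
        raise ValidationError(f"{name}: {exc}") from exc


def _parse_range(node: dict, name: str, probability: bool = True) -> AgeRange:
    low = float(_require(node, "low", name))
    high = float(_require(node, "high", name))
    if probability and not (0.0 <= low <= 1.0 and 0.0 <= high <= 1.0):
        raise ValidationError(f"{name}: range endpoints outside [0, 1]")
    try:
        return AgeRange(
            low=low,
            high=high,
            sd_low=float(node.get("sd_low", 0.0)),
            sd_high=float(node.get("sd_high", 0.0)),
            family=node.get("dist", "beta"),
        )
    except ValueError as exc:
        raise ValidationError(f"{name}: {exc}") from exc


def _build_life_table(cfg: dict, settings: Settings, base_dir: Path) -> LifeTable:
    from .synthetic import GompertzSpec, calibrate_gompertz, generate_life_table

    kind = _require(cfg, "kind", "life_table")
    if kind == "gompertz":
        if "hazard_at_start" in cfg:
            spec = GompertzSpec(
                hazard_at_start=float(cfg["hazard_at_start"]),
                doubling_years=float(cfg.get("doubling_years", 8.0)),
                start_age=settings.start_age,
                terminal_age=int(cfg.get("terminal_age", settings.max_age)),
            )
        else:
            spec = calibrate_gompertz(
                target_life_expectancy=float(
                    _require(cfg, "target_life_expectancy", "life_table")
                ),
                doubling_years=float(cfg.get("doubling_years", 8.0)),
                start_age=settings.start_age,
                terminal_age=int(cfg.get("terminal_age", settings.max_age)),
            )
        return generate_life_table(spec)
    if kind == "csv":
        path = Path(_require(cfg, "path", "life_table"))
        if not path.is_absolute():
            path = base_dir / path
        return LifeTable.from_csv(path)
    raise ValidationError(f"life_table.kind must be 'gompertz' or 'csv', got {kind!r}")


def parameters_from_dict(cfg: dict, base_dir: Path | None = None) -> ParameterSet:
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
    settings = Settings(**_require(cfg, "settings", "config"))
    life_table = _build_life_table(_require(cfg, "life_table", "config"), settings, base_dir)
    if life_table.terminal_age < settings.max_age:
        raise ValidationError(
            "life table must cover ages up to settings.max_age"
        )

    risks_cfg = _require(cfg, "baseline_risks", "config")
    baseline_risks = {}
    for event in EVENTS:
        node = _require(risks_cfg, event, "baseline_risks")
        name = f"baseline_risks.{event}"
        if "low" in node:
            baseline_risks[event] = _parse_range(node, name)
        else:
            baseline_risks[event] = _parse_spec(node, name, probability=True)

    util_cfg = _require(cfg, "utilities", "config")
    utilities = {
        key: _parse_spec(_require(util_cfg, key, "utilities"), f"utilities.{key}",
                         probability=True)
        for key in (
            "stroke", "hf", "acute_mi", "post_mi",
            "acute_angina", "post_angina", "pvd", "event_free",
        )
    }

    cost_cfg = _require(cfg, "state_costs", "config")
    state_costs = {
        key: _parse_spec(_require(cost_cfg, key, "state_costs"), f"state_costs.{key}")
        for key in ("stroke", "hf", "acute_mi", "acute_angina", "pvd")
    }

    prices_cfg = _require(cfg, "drug_prices", "config")
    drug_prices = {
        drug: {
            str(dose): _parse_spec(node, f"drug_prices.{drug}.{dose}")
            for dose, node in doses.items()
        }
        for drug, doses in prices_cfg.items()
    }

    effects_cfg = _require(cfg, "effects", "config")
    effects = {}
    for strat, evs in effects_cfg.items():
        effects[strat] = {}
        for event, node in evs.items():
            if event not in EVENTS:
                raise ValidationError(f"effects.{strat}.{event}: unknown event")
            effects[strat][event] = _parse_spec(node, f"effects.{strat}.{event}")

    mort_cfg = _require(cfg, "mortality", "config")
    fatal_mi_cfg = _require(mort_cfg, "fatal_mi", "mortality")
    mortality = MortalityBlock(
        fatal_stroke=_parse_spec(
            _require(mort_cfg, "fatal_stroke", "mortality"),
            "mortality.fatal_stroke", probability=True,
        ),
        fatal_hf=_parse_spec(
            _require(mort_cfg, "fatal_hf", "mortality"),
            "mortality.fatal_hf", probability=True,
        ),
        fatal_mi={
            sex: _parse_range(node, f"mortality.fatal_mi.{sex}")
            for sex, node in fatal_mi_cfg.items()
        },
        smr={
            k: _parse_spec(node, f"mortality.smr.{k}")
            for k, node in _require(mort_cfg, "smr", "mortality").items()
        },
        disease_specific_death=_parse_spec(
            _require(mort_cfg, "disease_specific_death", "mortality"),
            "mortality.disease_specific_death", probability=True,
        ),
    )
    if not set(mortality.fatal_mi) >= {"male", "female"}:
        raise ValidationError("mortality.fatal_mi must give male and female ranges")

    return ParameterSet(
        settings=settings,
        life_table=life_table,
        baseline_risks=baseline_risks,
        utilities=utilities,
        state_costs=state_costs,
        drug_prices=drug_prices,
        effects=effects,
        mortality=mortality,
        cost_components=cfg.get("cost_components", {}),
        life_table_config=dict(cfg.get("life_table", {})),
    )


def load_parameters(path) -> ParameterSet:
    """Load and validate a model configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = yaml.safe_load(path.read_text())
    return parameters_from_dict(cfg, base_dir=path.parent)


def load_base_case() -> ParameterSet:
    """The packaged base-case parameter set."""
    from .synthetic import base_config_dict

    return parameters_from_dict(base_config_dict())
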