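"""The six treatment arms and their effects and medication costs.

The combination arm (polypill: aspirin 81 mg, hydrochlorothiazide
12.5 mg, atorvastatin 20 mg, and valsartan 40 mg or enalapril 20 mg) is
compared against each component given alone.  Each arm carries a map of
relative effects on the five modelled events (pairs never studied default
to a null effect of 1.0) and a pack price.  Valsartan has no published
monotherapy effect block or pack price of its own, so it borrows the
enalapril block — the two drugs target the same renin-angiotensin
pathway and the trial treated them as interchangeable.

Annual medication cost supports three readings of the pack prices:

``per_tablet_daily``
    price / pack_size tablets, one dose per day, 365 days.
``per_pack_monthly``
    one pack per month.
``calibrated``
    per_tablet_daily scaled by ``settings.drug_cost_scale``.  Pack prices
    taken at face value are inconsistent with lifetime discounted totals
    of a few hundred USD, so the base case anchors the scale to the
    combination arm's published lifetime total (see calibration module).

Hydrochlorothiazide is dosed at 12.5 mg but only the 25 mg pack is
priced, so that arm uses half a tablet (half the per-tablet price) per
day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import DistributionSpec
from .parameters import ParameterSet, STRATEGY_LABELS
from .states import EVENTS

__all__ = [
    "Strategy",
    "effect_for",
    "annual_medication_cost",
    "build_strategy_set",
    "STRATEGY_LABELS",
]

#: (drug price key, dose key, tablets per day) for each monotherapy arm.
_MONOTHERAPY_DOSING = {
    "atorvastatin": ("atorvastatin", "20", 1.0),
    "hydrochlorothiazide": ("hydrochlorothiazide", "25", 0.5),  # 12.5 mg dose
    "aspirin": ("aspirin", "81", 1.0),
    "enalapril": ("enalapril", "20", 1.0),
    "valsartan": ("enalapril", "20", 1.0),  # no valsartan price published
}


@dataclass(frozen=True)
class Strategy:
    """One treatment arm: effects per event plus its medication pricing."""

    label: str
    effects: dict  # event -> DistributionSpec (complete after defaults)
    price: DistributionSpec  # USD per pack
    pack_size: int = 10
    tablets_per_day: float = 1.0

    def __post_init__(self) -> None:
        missing = set(EVENTS) - set(self.effects)
        if missing:
            raise ValueError(f"{self.label}: effects missing for {sorted(missing)}")

    def specified_events(self) -> list[str]:
        """Events with a genuinely studied (non-defaulted) effect."""
        return [e for e in EVENTS if not self.effects[e].is_fixed
                or self.effects[e].mean != 1.0]


def effect_for(strategy: Strategy, event: str) -> DistributionSpec:
    """The relative-effect spec of ``strategy`` on ``event`` (1.0 if absent)."""
    if event not in EVENTS:
        raise ValueError(f"unknown event {event!r}")
    return strategy.effects[event]


def annual_medication_cost(
    price_per_pack: float,
    pack_size: int,
    doses_per_day: float,
    cost_model: str,
    scale: float = 1.0,
) -> float:
    """Annual medication cost in USD under the chosen cost model."""
    if np.any(np.asarray(price_per_pack) < 0) or pack_size <= 0:
        raise ValueError("price must be non-negative and pack size positive")
    per_tablet_daily = price_per_pack / pack_size * 365.0 * doses_per_day
    if cost_model == "per_tablet_daily":
        return per_tablet_daily
    if cost_model == "per_pack_monthly":
        return price_per_pack * 12.0
    if cost_model == "calibrated":
        return per_tablet_daily * scale
    raise ValueError(f"unknown cost model {cost_model!r}")


def build_strategy_set(
    params: ParameterSet, polypill_variant: str | None = None
) -> list[Strategy]:
    """All six arms resolved against a parameter set.

    ``polypill_variant`` picks the enalapril- (E) or valsartan-based (V)
    combination price; the default comes from the settings block.
    """
    variant = polypill_variant or params.settings.polypill_variant
    if variant not in ("E", "V"):
        raise ValueError("polypill_variant must be 'E' or 'V'")

    strategies = []
    for label in STRATEGY_LABELS:
        effect_source = "enalapril" if label == "valsartan" else label
        effects = {
            event: params.effect_spec(effect_source, event) for event in EVENTS
        }
        if label == "polypill":
            drug, dose, tablets = f"polypill_{variant.lower()}", "1", 1.0
        else:
            drug, dose, tablets = _MONOTHERAPY_DOSING[label]
        try:
            price = params.drug_prices[drug][dose]
        except KeyError as exc:
            raise ValueError(
                f"no price for {label}: drug_prices.{drug}.{dose} missing"
            ) from exc
        strategies.append(
            Strategy(
                label=label,
                effects=effects,
                price=price,
                pack_size=10,
                tablets_per_day=tablets,
            )
        )
    return strategies
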