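from __future__ import annotations

import numpy as np
import pytest

import polypill_cea as pc
from polypill_cea.distributions import DistributionSpec
from polypill_cea.lifetable import LifeTable
from polypill_cea.parameters import AgeRange, MortalityBlock, ParameterSet, Settings


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    """The shipped base-case parameter set (drug-cost scale as calibrated)."""
    return pc.load_base_case()


@pytest.fixture(scope="session")
def base_strategies(base_params):
    return pc.build_strategy_set(base_params)


def make_minimal_params(
    *,
    start_age: int = 35,
    max_age: int = 45,
    qx: float = 0.0,
    discount_cost: float = 0.0,
    discount_qaly: float = 0.0,
    stroke_risk: float = 0.0,
    fatal_stroke: float = 0.0,
    smr_stroke: float = 1.0,
    stroke_cost: float = 0.0,
    stroke_utility: float = 1.0,
    half_cycle: bool = False,
    drug_price: float = 0.0,
) -> ParameterSet:
    """A degenerate parameter set for closed-form and oracle chains.

    Only the stroke pathway can be switched on; every other event risk is
    zero, so at most three states (event-free, stroke, dead) are ever
    occupied.
    """
    fixed = lambda x: DistributionSpec("fixed", x, 0.0)
    T = max_age - start_age
    ages = np.arange(start_age, max_age + 1)
    qxs = np.full(ages.shape, float(qx))
    qxs[-1] = 1.0
    lt = LifeTable(ages=ages, qx=qxs)
    settings = Settings(
        start_age=start_age,
        max_age=max_age,
        discount_cost=discount_cost,
        discount_qaly=discount_qaly,
        half_cycle_correction=half_cycle,
        cost_model="per_tablet_daily",
        drug_cost_scale=1.0,
        risk_span_end=max_age,
    )
    prices = {
        drug: {dose: fixed(drug_price)}
        for drug, dose in [
            ("polypill_v", "1"), ("polypill_e", "1"), ("atorvastatin", "20"),
            ("hydrochlorothiazide", "25"), ("aspirin", "81"), ("enalapril", "20"),
        ]
    }
    return ParameterSet(
        settings=settings,
        life_table=lt,
        baseline_risks={
            "stroke": fixed(stroke_risk),
            "hf": fixed(0.0),
            "mi": fixed(0.0),
            "angina": fixed(0.0),
            "pvd": fixed(0.0),
        },
        utilities={
            "stroke": fixed(stroke_utility),
            "hf": fixed(1.0),
            "acute_mi": fixed(1.0),
            "post_mi": fixed(1.0),
            "acute_angina": fixed(1.0),
            "post_angina": fixed(1.0),
            "pvd": fixed(1.0),
            "event_free": fixed(1.0),
        },
        state_costs={
            "stroke": fixed(stroke_cost),
            "hf": fixed(0.0),
            "acute_mi": fixed(0.0),
            "acute_angina": fixed(0.0),
            "pvd": fixed(0.0),
        },
        drug_prices=prices,
        effects={},
        mortality=MortalityBlock(
            fatal_stroke=fixed(fatal_stroke),
            fatal_hf=fixed(0.0),
            fatal_mi={
                "male": AgeRange(0.0, 0.0),
                "female": AgeRange(0.0, 0.0),
            },
            smr={
                "stroke": fixed(smr_stroke),
                "hf": fixed(1.0),
                "mi": fixed(1.0),
                "angina": fixed(1.0),
                "pvd": fixed(1.0),
            },
            disease_specific_death=fixed(0.0),
        ),
    )


@pytest.fixture
def minimal_params():
    return make_minimal_params
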