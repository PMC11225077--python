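"""Health-state space of the cardiovascular Markov model.

The cohort model tracks a single entry state (event-free), five chronic
disease states (stroke, heart failure, post-MI, post-angina, peripheral
vascular disease), two one-cycle acute "tunnel" states that price the
event year of MI and angina separately, and an absorbing dead state.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """Model states; integer values index occupancy vectors and matrices."""

    EVENT_FREE = 0
    STROKE = 1
    HF = 2
    ACUTE_MI = 3
    POST_MI = 4
    ACUTE_ANGINA = 5
    POST_ANGINA = 6
    PVD = 7
    DEAD = 8


N_STATES = len(HealthState)

#: Acute events a person in the event-free state can experience in a cycle.
EVENTS = ("stroke", "hf", "mi", "angina", "pvd")

#: Event -> state entered when the event is not immediately fatal.
EVENT_ENTRY_STATE = {
    "stroke": HealthState.STROKE,
    "hf": HealthState.HF,
    "mi": HealthState.ACUTE_MI,
    "angina": HealthState.ACUTE_ANGINA,
    "pvd": HealthState.PVD,
}

#: Events with a case-fatality probability (the fatal share goes straight
#: to DEAD in the event cycle).
FATAL_EVENTS = ("stroke", "hf", "mi")

#: Chronic states: transition only to themselves or to DEAD.
CHRONIC_STATES = (
    HealthState.STROKE,
    HealthState.HF,
    HealthState.POST_MI,
    HealthState.POST_ANGINA,
    HealthState.PVD,
)

#: One-cycle tunnel states and the chronic state each feeds.
TUNNEL_SUCCESSOR = {
    HealthState.ACUTE_MI: HealthState.POST_MI,
    HealthState.ACUTE_ANGINA: HealthState.POST_ANGINA,
}

#: Disease label used for excess (SMR) mortality in each non-dead state.
STATE_SMR_DISEASE = {
    HealthState.STROKE: "stroke",
    HealthState.HF: "hf",
    HealthState.ACUTE_MI: "mi",
    HealthState.POST_MI: "mi",
    HealthState.ACUTE_ANGINA: "angina",
    HealthState.POST_ANGINA: "angina",
    HealthState.PVD: "pvd",
}
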