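"""Markov health states and the extended (treatment-tunnel) state space."""

from __future__ import annotations

import enum

__all__ = [
    "HealthState",
    "BASE_STATES",
    "DEMENTIA_STATES",
    "EXT_STATES",
    "EXT_INDEX",
    "TUNNEL_STATES",
    "BASE_OF",
]


class HealthState(str, enum.Enum):
    """The nine disease states of the annual progression model."""

    SCD = "SCD"
    MCI = "MCI"
    MILD = "MILD"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"
    MILD_LTC = "MILD_LTC"
    MODERATE_LTC = "MODERATE_LTC"
    SEVERE_LTC = "SEVERE_LTC"
    DEAD = "DEAD"


BASE_STATES: tuple[HealthState, ...] = tuple(HealthState)

#: The six clinical-dementia states (community and long-term care).
DEMENTIA_STATES: tuple[HealthState, ...] = (
    HealthState.MILD,
    HealthState.MODERATE,
    HealthState.SEVERE,
    HealthState.MILD_LTC,
    HealthState.MODERATE_LTC,
    HealthState.SEVERE_LTC,
)

#: Treatment tunnel copies of MCI and mild dementia, indexed by treatment
#: year. A memoryless nine-state chain cannot express "two years of therapy
#: or until moderate dementia", so on-treatment occupancy lives in these
#: copies and reverts to the plain states when the tunnel ends.
TUNNEL_STATES: tuple[str, ...] = ("MCI_TX1", "MCI_TX2", "MILD_TX1", "MILD_TX2")

#: Full simulation state space: nine base states plus the four tunnels.
EXT_STATES: tuple[str, ...] = tuple(s.value for s in BASE_STATES) + TUNNEL_STATES
EXT_INDEX: dict[str, int] = {name: i for i, name in enumerate(EXT_STATES)}

#: Map from extended state name to the base health state it represents.
BASE_OF: dict[str, HealthState] = {s.value: s for s in BASE_STATES}
BASE_OF.update(
    {
        "MCI_TX1": HealthState.MCI,
        "MCI_TX2": HealthState.MCI,
        "MILD_TX1": HealthState.MILD,
        "MILD_TX2": HealthState.MILD,
    }
)
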