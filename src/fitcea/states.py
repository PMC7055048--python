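"""Health-state space of the physical-activity Markov model.

Nine mutually exclusive states: three physical-activity levels (classified
from self-reported MET-min per week: inactive < 200, moderately active
200-450, recommended > 450), five chronic conditions associated with lack of
physical activity, and death. Disease states can only be entered from an
activity state and left only through death; death is absorbing.
"""

from __future__ import annotations

import enum


class HealthState(str, enum.Enum):
    INACTIVE = "inactive"
    MODERATE = "moderate"
    RECOMMENDED = "recommended"
    COLORECTAL_CANCER = "colorectal_cancer"
    CHD = "chd"
    T2D = "t2d"
    STROKE = "stroke"
    DEPRESSION = "depression"
    DEAD = "dead"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def category(self) -> str:
        if self in ACTIVITY_STATES:
            return "activity"
        if self in DISEASE_STATES:
            return "disease"
        return "absorbing"


ACTIVITY_STATES: tuple[HealthState, ...] = (
    HealthState.INACTIVE,
    HealthState.MODERATE,
    HealthState.RECOMMENDED,
)

DISEASE_STATES: tuple[HealthState, ...] = (
    HealthState.COLORECTAL_CANCER,
    HealthState.CHD,
    HealthState.T2D,
    HealthState.STROKE,
    HealthState.DEPRESSION,
)

#: Canonical state ordering used for every matrix and trace in the package.
STATE_ORDER: tuple[HealthState, ...] = ACTIVITY_STATES + DISEASE_STATES + (HealthState.DEAD,)

N_STATES = len(STATE_ORDER)

STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

ARMS = ("eurofit", "control")
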