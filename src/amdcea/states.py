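"""Health states, strategies, and lesion subtypes.

Visual acuity (VA) is banded on the Snellen chart of the better-seeing eye.
Each band spans roughly one Snellen doubling (~3 lines), so a gain of more
than 3 lines moves the cohort one band up, a loss of 3-6 lines one band down,
and a loss of more than 6 lines two bands down.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """Six model states: five VA bands (best to worst) plus absorbing death."""

    VA_BETTER_20_40 = 0      # SCVA > 20/40
    VA_20_40_TO_20_80 = 1    # <= 20/40 to > 20/80
    VA_20_80_TO_20_200 = 2   # <= 20/80 to > 20/200
    VA_20_200_TO_20_400 = 3  # <= 20/200 to > 20/400
    VA_20_400_OR_WORSE = 4   # <= 20/400 (light perception only)
    DEAD = 5


N_STATES = len(HealthState)
N_VA_STATES = N_STATES - 1
DEAD_INDEX = int(HealthState.DEAD)

#: VA states counted as "seeing" for the vision-years metric (better than 20/200).
DEFAULT_VISION_STATES = (0, 1, 2)

#: VA states that incur comorbidity costs by default (<= 20/80 and worse).
DEFAULT_COMORBIDITY_STATES = (2, 3, 4)


class Strategy(str, enum.Enum):
    USUAL_CARE = "usual_care"
    PDT = "pdt"
    RANIBIZUMAB = "ranibizumab"
    BEVACIZUMAB = "bevacizumab"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Lesion(str, enum.Enum):
    PREDOMINANTLY_CLASSIC = "predominantly_classic"
    MINIMALLY_CLASSIC = "minimally_classic"
    OCCULT = "occult"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ACTIVE_INJECTION_STRATEGIES = (Strategy.RANIBIZUMAB, Strategy.BEVACIZUMAB)
ALL_STRATEGIES = tuple(Strategy)
ALL_LESIONS = tuple(Lesion)
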