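"""Design assumptions for the packaged LV-thrombus evidence base.

These are the event proportions the source analysis assumed when sizing
each outcome's required information: the superiority assumptions (distinct
DOAC and VKA rates defining the detectable risk difference) and, for the
futility simulations, a common rate under no treatment difference.
"""

from __future__ import annotations

from .information_size import RISSpec
from .trial_data import Outcome

__all__ = ["DESIGN_PROPORTIONS", "NULL_SCENARIO_RATES", "design_spec"]

# (intervention rate, control rate) assumed for the required information size
DESIGN_PROPORTIONS: dict[Outcome, tuple[float, float]] = {
    Outcome.THROMBUS_RESOLUTION: (0.74, 0.68),
    Outcome.STROKE: (0.07, 0.10),
    Outcome.ANY_THROMBOEMBOLISM: (0.16, 0.21),
    Outcome.MAJOR_BLEEDING: (0.02, 0.04),
    Outcome.ANY_BLEEDING: (0.08, 0.10),
    Outcome.ALL_CAUSE_DEATH: (0.06, 0.10),
}

# common event rate assumed in both arms for futility (no-difference) simulations
NULL_SCENARIO_RATES: dict[Outcome, float] = {
    Outcome.THROMBUS_RESOLUTION: 0.70,
    Outcome.STROKE: 0.08,
    Outcome.ANY_THROMBOEMBOLISM: 0.20,
    Outcome.MAJOR_BLEEDING: 0.03,
    Outcome.ANY_BLEEDING: 0.10,
    Outcome.ALL_CAUSE_DEATH: 0.08,
}


def design_spec(outcome: Outcome, alpha: float = 0.05, power: float = 0.80) -> RISSpec:
    """Required-information-size spec under the outcome's design assumptions."""
    p_int, p_ctl = DESIGN_PROPORTIONS[outcome]
    return RISSpec(p_int=p_int, p_ctl=p_ctl, alpha=alpha, power=power)
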