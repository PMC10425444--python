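"""Required information size (RIS) for a two-proportion comparison.

The RIS plays the role a sample-size calculation plays for a single trial:
the total number of patients a cumulative meta-analysis needs before a
two-sided level-alpha test has the requested power against the assumed
difference in event proportions. The unadjusted form is the textbook
normal-approximation two-proportion size with pooled variance,

    N = 4 (z_{1-alpha/2} + z_{power})^2  p̄(1-p̄) / delta^2,

total across both arms under 1:1 allocation, with p̄ the mean of the two
assumed proportions and delta their difference. Between-trial heterogeneity
dilutes information, so the diversity-adjusted size divides by (1 - D^2),
where D^2 is the diversity of the evidence base being monitored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

__all__ = ["RISSpec", "required_information_size"]


@dataclass(frozen=True)
class RISSpec:
    """Assumptions anchoring a required-information-size calculation.

    ``p_int``/``p_ctl`` are the assumed event proportions, ``alpha`` the
    two-sided type-1 error, ``power`` the target power, and ``d2`` the
    diversity used for heterogeneity adjustment (0 = no adjustment).
    """

    p_int: float
    p_ctl: float
    alpha: float = 0.05
    power: float = 0.80
    d2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_int", "p_ctl", "alpha", "power"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.p_int == self.p_ctl:
            raise ValueError("p_int and p_ctl must differ (no effect to detect)")
        if self.alpha + (1.0 - self.power) >= 1.0:
            raise ValueError("alpha + beta must be below 1")
        if not (0.0 <= self.d2 < 1.0):
            raise ValueError("d2 must lie in [0, 1); at 1 information never suffices")

    @property
    def drift(self) -> float:
        """Mean of the Brownian monitoring statistic at full information
        under the design alternative: z_{1-alpha/2} + z_{power}."""
        return float(stats.norm.ppf(1 - self.alpha / 2) + stats.norm.ppf(self.power))

    def with_d2(self, d2: float) -> "RISSpec":
        return replace(self, d2=d2)


def required_information_size(spec: RISSpec) -> int:
    """Total patients required (both arms, 1:1), diversity-adjusted.

    The ceiling is applied once, after the 1/(1-D^2) adjustment.
    """
    p_bar = 0.5 * (spec.p_int + spec.p_ctl)
    delta = abs(spec.p_int - spec.p_ctl)
    n_unadj = 4.0 * spec.drift**2 * p_bar * (1.0 - p_bar) / delta**2
    return math.ceil(n_unadj / (1.0 - spec.d2))
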