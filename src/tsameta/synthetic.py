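"""Synthetic two-arm binary-outcome trial series with known truth.

Emulates the structure of a real evidence base — a mix of small and
mid-sized two-arm studies accruing over time — with a configurable true
odds ratio, between-trial heterogeneity on the log-odds scale (normal
random effects, the scale on which DerSimonian-Laird pools), a control-arm
event rate, and an arm-size law. Default arm sizes are lognormal
(mu = ln 60, sigma = 0.6), rounded, floored at 4 per arm, mimicking the
spread of published series (a few patients up to several hundred per arm).

All randomness flows from a single seed through counter-based per-trial
substreams, so regenerating with the same seed is byte-identical and the
i-th trial does not depend on how many trials are requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .trial_data import Design, Outcome, OutcomeDataset, TwoByTwoTrial

__all__ = ["SyntheticConfig", "generate_series"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating truth for a synthetic trial series."""

    n_trials: int
    true_log_or: float = 0.0
    tau2: float = 0.0
    p_ctl: float = 0.3
    arm_size_law: str = "lognormal"  # "fixed" or "lognormal"
    arm_size: int = 60  # per arm; the fixed size, or ignored for lognormal
    lognormal_mu: float = math.log(60.0)
    lognormal_sigma: float = 0.6
    min_arm_size: int = 4
    seed: int = 0
    start_year: int = 2000
    outcome: Outcome = Outcome.THROMBUS_RESOLUTION

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not (0.0 < self.p_ctl < 1.0):
            raise ValueError("p_ctl must lie in (0, 1)")
        if self.arm_size_law not in ("fixed", "lognormal"):
            raise ValueError("arm_size_law must be 'fixed' or 'lognormal'")
        if self.arm_size_law == "fixed" and self.arm_size < 1:
            raise ValueError("fixed arm_size must be >= 1")


def generate_series(config: SyntheticConfig) -> OutcomeDataset:
    """Draw one trial series under the configured truth.

    Per trial i: theta_i ~ N(true_log_or, tau2); control events are
    Binomial(n_ctl, p_ctl); intervention events are Binomial(n_int, p_i)
    with logit(p_i) = logit(p_ctl) + theta_i.
    """
    width = max(4, len(str(config.n_trials)))
    trials = []
    base = logit(config.p_ctl)
    tau = math.sqrt(config.tau2)
    for i in range(config.n_trials):
        rng = np.random.default_rng([config.seed, i])  # per-trial substream
        if config.arm_size_law == "fixed":
            n_int = n_ctl = config.arm_size
        else:
            sizes = np.maximum(
                np.rint(
                    np.exp(rng.normal(config.lognormal_mu, config.lognormal_sigma, 2))
                ).astype(int),
                config.min_arm_size,
            )
            n_int, n_ctl = int(sizes[0]), int(sizes[1])
        theta_i = config.true_log_or + (tau * rng.standard_normal() if tau else 0.0)
        p_i = float(expit(base + theta_i))
        e_ctl = int(rng.binomial(n_ctl, config.p_ctl))
        e_int = int(rng.binomial(n_int, p_i))
        trials.append(
            TwoByTwoTrial(
                study_id=f"sim_{i + 1:0{width}d}",
                year=config.start_year,
                design=Design.RCT,
                n_int=n_int,
                e_int=e_int,
                n_ctl=n_ctl,
                e_ctl=e_ctl,
            )
        )
    return OutcomeDataset(outcome=config.outcome, trials=tuple(trials))
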