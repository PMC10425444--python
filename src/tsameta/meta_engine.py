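"""Per-study odds ratios, DerSimonian-Laird random-effects pooling, and the
cumulative Z-curve.

Effect sizes are log odds ratios from 2x2 tables with a Haldane-Anscombe
continuity correction (add 0.5 to every cell when any cell is zero).
Pooling is inverse-variance DerSimonian-Laird: the between-study variance
tau^2 is the method-of-moments estimate from Cochran's Q, and the diversity
D^2 = 1 - v_fixed/v_random is the fraction of the random-effects pooled
variance attributable to between-study variation (the information-size
inflation factor used by trial sequential analysis).

Studies with zero events in both arms (or events in every patient of both
arms) carry no effect-size information; they are excluded from pooling but
their patients still count toward the accrued information of the Z-curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import OutcomeDataset, TwoByTwoTrial

__all__ = [
    "EffectEstimate",
    "PooledResult",
    "CumulativePoint",
    "NoInformationError",
    "effect_from_2x2",
    "pool_dl",
    "cumulative_curve",
    "forest_table",
]

logger = logging.getLogger(__name__)

Z_975 = stats.norm.ppf(0.975)


class NoInformationError(ValueError):
    """Raised for double-zero / double-full tables: the log odds ratio is
    undefined, so the study cannot contribute an effect size."""


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio (intervention vs control) and its variance."""

    log_or: float
    var: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValueError("log_or must be finite")
        if not (self.var > 0):
            raise ValueError("var must be positive")


@dataclass(frozen=True)
class PooledResult:
    """Random-effects summary for k pooled studies.

    ``theta``/``se``/``z`` are on the log-OR scale; ``ci_low``/``ci_high``
    on the OR scale. ``q`` is Cochran's Q, ``i2`` the usual heterogeneity
    fraction, ``d2`` the diversity used for information-size adjustment.
    """

    k: int
    theta: float
    se: float
    z: float
    ci_low: float
    ci_high: float
    q: float
    tau2: float
    i2: float
    d2: float

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta)

    @property
    def p_value(self) -> float:
        return 2 * stats.norm.sf(abs(self.z))


@dataclass(frozen=True)
class CumulativePoint:
    """One interim look of the cumulative meta-analysis.

    ``z_signed`` is oriented so that positive always favours the
    intervention, regardless of whether events are desirable.
    """

    look_index: int
    cumulative_n: int
    z_signed: float
    theta_cum: float
    se_cum: float
    pooled: PooledResult


def effect_from_2x2(trial: TwoByTwoTrial, correction: float = 0.5) -> EffectEstimate:
    """Log odds ratio and variance from one 2x2 table.

    With cells a = events(int), b = non-events(int), c = events(ctl),
    d = non-events(ctl): log OR = ln(ad/bc), var = 1/a + 1/b + 1/c + 1/d.
    If any cell is zero, ``correction`` is first added to all four cells.
    """
    if correction < 0:
        raise ValueError("correction must be >= 0")
    if trial.no_information:
        raise NoInformationError(
            f"{trial.study_id}: table carries no effect-size information "
            "(zero or full events in both arms)"
        )
    a = float(trial.e_int)
    b = float(trial.n_int - trial.e_int)
    c = float(trial.e_ctl)
    d = float(trial.n_ctl - trial.e_ctl)
    corrected = False
    if min(a, b, c, d) == 0.0:
        if correction == 0:
            raise ZeroDivisionError(
                f"{trial.study_id}: zero cell with no continuity correction"
            )
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
        corrected = True
    log_or = math.log((a * d) / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectEstimate(log_or=log_or, var=var, corrected=corrected)


def pool_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance DerSimonian-Laird random-effects pooling."""
    k = len(effects)
    if k == 0:
        raise ValueError("cannot pool zero effects")
    theta_i = np.array([e.log_or for e in effects])
    v_i = np.array([e.var for e in effects])

    w = 1.0 / v_i
    sw = w.sum()
    theta_f = float((w * theta_i).sum() / sw)
    q = float((w * (theta_i - theta_f) ** 2).sum())
    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v_i + tau2)
    sw_star = w_star.sum()
    theta = float((w_star * theta_i).sum() / sw_star)
    se = float(sw_star ** (-0.5))
    z = theta / se

    v_fixed = 1.0 / sw
    v_random = 1.0 / sw_star
    d2 = 0.0 if tau2 == 0.0 else 1.0 - v_fixed / v_random
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0

    return PooledResult(
        k=k,
        theta=theta,
        se=se,
        z=z,
        ci_low=math.exp(theta - Z_975 * se),
        ci_high=math.exp(theta + Z_975 * se),
        q=q,
        tau2=tau2,
        i2=i2,
        d2=d2,
    )


def cumulative_curve(
    dataset: OutcomeDataset, correction: float = 0.5
) -> list[CumulativePoint]:
    """Pooled Z after each added trial, in canonical chronological order.

    Each trial is one interim look. Trials with no effect-size information
    are skipped in the pooling but their patients accrue to ``cumulative_n``
    (information in trial sequential analysis counts patients). Looks before
    the first pool-eligible trial are omitted.
    """
    points: list[CumulativePoint] = []
    effects: list[EffectEstimate] = []
    cum_n = 0
    sign = 1.0 if dataset.events_desirable else -1.0
    for i, trial in enumerate(dataset.trials, start=1):
        cum_n += trial.n_total
        if not trial.no_information:
            effects.append(effect_from_2x2(trial, correction=correction))
        if not effects:
            continue
        pooled = pool_dl(effects)
        points.append(
            CumulativePoint(
                look_index=i,
                cumulative_n=cum_n,
                z_signed=sign * pooled.z,
                theta_cum=pooled.theta,
                se_cum=pooled.se,
                pooled=pooled,
            )
        )
    if not points:
        logger.warning(
            "dataset %s has no pool-eligible trials; empty curve",
            dataset.outcome.value,
        )
    return points


def forest_table(dataset: OutcomeDataset, correction: float = 0.5) -> pd.DataFrame:
    """Per-study OR, 95% CI and random-effects weight, plus a pooled row.

    The export behind forest plots; weights are normalised random-effects
    weights in percent. No-information studies appear with NaN effect
    columns and zero weight.
    """
    eligible = [t for t in dataset.trials if not t.no_information]
    effects = [effect_from_2x2(t, correction=correction) for t in eligible]
    pooled = pool_dl(effects)
    w_star = np.array([1.0 / (e.var + pooled.tau2) for e in effects])
    w_pct = 100.0 * w_star / w_star.sum()
    weights = {t.study_id: w for t, w in zip(eligible, w_pct)}
    ors = {t.study_id: math.exp(e.log_or) for t, e in zip(eligible, effects)}
    lo = {
        t.study_id: math.exp(e.log_or - Z_975 * math.sqrt(e.var))
        for t, e in zip(eligible, effects)
    }
    hi = {
        t.study_id: math.exp(e.log_or + Z_975 * math.sqrt(e.var))
        for t, e in zip(eligible, effects)
    }
    rows = [
        {
            "study_id": t.study_id,
            "year": t.year,
            "or": ors.get(t.study_id, float("nan")),
            "ci_low": lo.get(t.study_id, float("nan")),
            "ci_high": hi.get(t.study_id, float("nan")),
            "weight_pct": weights.get(t.study_id, 0.0),
        }
        for t in dataset.trials
    ]
    rows.append(
        {
            "study_id": "RE pooled",
            "year": pd.NA,
            "or": pooled.odds_ratio,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
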