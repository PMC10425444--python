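"""Join the cumulative Z-curve, the required information size, and the
monitoring boundaries into a four-way conclusiveness verdict.

The verdict vocabulary follows the standard trial-sequential-analysis
schema: crossing the superiority boundary is conclusive evidence of an
effect (*true positive*); entering the futility wedge is conclusive
evidence of no worthwhile effect (*true negative*); crossing only the
traditional fixed-sample line Z = +-1.96 is a potentially spurious finding
(*false positive*); crossing nothing is simply insufficient evidence
(*false negative*).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .boundaries import MonitoringPlan, build_monitoring_plan
from .information_size import RISSpec, required_information_size
from .meta_engine import CumulativePoint, cumulative_curve, pool_dl, effect_from_2x2
from .trial_data import OutcomeDataset

__all__ = ["Crossing", "Classification", "TSAVerdict", "classify", "run_tsa"]


class Crossing(str, Enum):
    SUPERIORITY = "superiority"
    FUTILITY = "futility"
    TRADITIONAL_ONLY = "traditional_only"
    NONE = "none"


class Classification(str, Enum):
    TRUE_POSITIVE = "true_positive"
    TRUE_NEGATIVE = "true_negative"
    FALSE_POSITIVE = "false_positive"
    FALSE_NEGATIVE = "false_negative"


_CROSSING_TO_CLASS = {
    Crossing.SUPERIORITY: Classification.TRUE_POSITIVE,
    Crossing.FUTILITY: Classification.TRUE_NEGATIVE,
    Crossing.TRADITIONAL_ONLY: Classification.FALSE_POSITIVE,
    Crossing.NONE: Classification.FALSE_NEGATIVE,
}


@dataclass(frozen=True)
class TSAVerdict:
    """Conclusiveness verdict for one outcome's evidence base."""

    outcome: str
    ris: int
    accrued_n: int
    accrued_fraction: float
    crossing: Crossing
    classification: Classification
    crossing_look: int | None
    final_z: float

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "ris": self.ris,
            "accrued_n": self.accrued_n,
            "accrued_fraction": self.accrued_fraction,
            "crossing": self.crossing.value,
            "classification": self.classification.value,
            "crossing_look": self.crossing_look,
            "final_z": self.final_z,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=1)

    def summary(self) -> str:
        lines = [
            f"Outcome: {self.outcome}",
            f"  accrued patients: {self.accrued_n} of required {self.ris} "
            f"({100 * self.accrued_fraction:.0f}%)",
            f"  final signed Z: {self.final_z:+.2f}",
            f"  crossing: {self.crossing.value}"
            + (f" at look {self.crossing_look}" if self.crossing_look else ""),
            f"  verdict: {self.classification.value.replace('_', ' ')}",
        ]
        return "\n".join(lines)


def classify(
    curve: Sequence[CumulativePoint],
    plan: MonitoringPlan,
    ris: int,
    outcome: str = "",
) -> TSAVerdict:
    """Scan looks in order and return the first conclusive crossing.

    Superiority is checked before futility at each look; a conclusive
    crossing (superiority or futility) stops the scan — later looks never
    revise it. The fallback hierarchy is traditional-only, then none.
    Crossings are assessed only at look points, never by interpolation.
    """
    if len(curve) != plan.n_looks:
        raise ValueError(
            f"curve has {len(curve)} looks but plan has {plan.n_looks}"
        )
    crossing = Crossing.NONE
    crossing_look: int | None = None
    hit_traditional: int | None = None
    for point, sup, fut in zip(curve, plan.sup_bounds, plan.fut_bounds):
        z = point.z_signed
        if abs(z) >= sup:
            crossing, crossing_look = Crossing.SUPERIORITY, point.look_index
            break
        if fut is not None and abs(z) < fut:
            crossing, crossing_look = Crossing.FUTILITY, point.look_index
            break
        if hit_traditional is None and abs(z) >= plan.traditional:
            hit_traditional = point.look_index
    if crossing is Crossing.NONE and hit_traditional is not None:
        crossing, crossing_look = Crossing.TRADITIONAL_ONLY, hit_traditional
    accrued_n = curve[-1].cumulative_n if curve else 0
    return TSAVerdict(
        outcome=outcome,
        ris=ris,
        accrued_n=accrued_n,
        accrued_fraction=accrued_n / ris,
        crossing=crossing,
        classification=_CROSSING_TO_CLASS[crossing],
        crossing_look=crossing_look,
        final_z=curve[-1].z_signed if curve else float("nan"),
    )


def run_tsa(
    dataset: OutcomeDataset,
    ris_spec: RISSpec,
    data_driven_d2: bool = True,
    correction: float = 0.5,
    with_futility: bool = True,
    n_nodes: int | None = None,
) -> tuple[TSAVerdict, MonitoringPlan, list[CumulativePoint]]:
    """Full trial sequential analysis of one outcome dataset.

    When ``data_driven_d2`` is set, the diversity D^2 of the full-dataset
    random-effects pooling replaces ``ris_spec.d2`` before the required
    information size is computed; the spending boundaries are then placed
    at one look per trial.
    """
    curve = cumulative_curve(dataset, correction=correction)
    if not curve:
        raise ValueError(f"no pool-eligible trials for {dataset.outcome.value}")
    spec = ris_spec
    if data_driven_d2:
        effects = [
            effect_from_2x2(t, correction=correction)
            for t in dataset.trials
            if not t.no_information
        ]
        spec = ris_spec.with_d2(pool_dl(effects).d2)
    ris = required_information_size(spec)
    kwargs = {} if n_nodes is None else {"n_nodes": n_nodes}
    plan = build_monitoring_plan(
        [p.cumulative_n for p in curve],
        ris,
        alpha=spec.alpha,
        power=spec.power,
        with_futility=with_futility,
        **kwargs,
    )
    verdict = classify(curve, plan, ris, outcome=dataset.outcome.value)
    return verdict, plan, curve
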