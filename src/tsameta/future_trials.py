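"""Simulated-future-trial sample-size estimation.

Given an existing evidence base, append hypothetical trials at assumed
event rates and find the minimal additional sample size at which the
cumulative Z-curve crosses a chosen monitoring boundary. Appended trials
are deterministic "expected-count" trials — event counts are the rounded
expectation rate x arm size — so the answer is a single number rather than
a distribution; a seeded stochastic mode drawing binomial event counts is
available for sensitivity analysis.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .information_size import RISSpec
from .trial_data import Design, OutcomeDataset, TwoByTwoTrial
from .tsa_engine import Crossing, run_tsa

__all__ = ["FutureTrialPlan", "FutureTrialResult", "estimate_additional_n"]


@dataclass(frozen=True)
class FutureTrialPlan:
    """Recipe for the appended-trial search.

    ``increment`` is the total patients per appended trial (split 1:1);
    ``target`` is the boundary the search aims for; ``ris_spec`` carries the
    design assumptions anchoring the required information size (its
    diversity is re-derived from the augmented data unless
    ``data_driven_d2`` is off).
    """

    base: OutcomeDataset
    rate_int: float
    rate_ctl: float
    target: Crossing
    increment: int = 100
    max_added: int = 40_000
    ris_spec: RISSpec = None  # type: ignore[assignment]
    data_driven_d2: bool = True
    stochastic: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ris_spec is None:
            raise ValueError("ris_spec is required")
        if len(self.base) == 0:
            raise ValueError("base dataset must be non-empty")
        for name in ("rate_int", "rate_ctl"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.target not in (Crossing.SUPERIORITY, Crossing.FUTILITY):
            raise ValueError("target must be superiority or futility")
        if self.increment < 2 or self.increment % 2:
            raise ValueError("increment must be an even integer >= 2")
        if self.max_added < self.increment:
            raise ValueError("max_added must be at least one increment")


@dataclass(frozen=True)
class FutureTrialResult:
    """Outcome of the search.

    ``added_n`` is the smallest total appended patients at which the target
    boundary is crossed, or ``None`` if it is unreachable (opposite
    conclusive boundary hit first, or ``max_added`` exhausted);
    ``terminal_crossing`` is the conclusive crossing in force when the
    search ended.
    """

    added_n: int | None
    looks_added: int
    terminal_crossing: Crossing
    trajectory: tuple[dict, ...] = field(default=(), repr=False)

    @property
    def unreachable(self) -> bool:
        return self.added_n is None


def _synthetic_trials(plan: FutureTrialPlan) -> Iterator[TwoByTwoTrial]:
    """Endless stream of appended trials, years past the base's last year."""
    per_arm = plan.increment // 2
    year0 = max(t.year for t in plan.base.trials) + 1
    rng = np.random.default_rng(plan.seed) if plan.stochastic else None
    i = 0
    while True:
        i += 1
        if rng is None:
            e_int = round(plan.rate_int * per_arm)
            e_ctl = round(plan.rate_ctl * per_arm)
        else:
            e_int = int(rng.binomial(per_arm, plan.rate_int))
            e_ctl = int(rng.binomial(per_arm, plan.rate_ctl))
        yield TwoByTwoTrial(
            study_id=f"sim_{i:05d}",
            year=year0 + i - 1,
            design=Design.RCT,
            n_int=per_arm,
            e_int=e_int,
            n_ctl=per_arm,
            e_ctl=e_ctl,
        )


def _first_conclusive(verdict) -> Crossing:
    return verdict.crossing if verdict.crossing in (
        Crossing.SUPERIORITY,
        Crossing.FUTILITY,
    ) else Crossing.NONE


def estimate_additional_n(plan: FutureTrialPlan) -> FutureTrialResult:
    """Minimal appended sample size to cross the target boundary.

    After each appended trial the cumulative curve, the (optionally
    diversity-readjusted) required information size, and the spending
    boundaries are all recomputed from scratch on the augmented series,
    and the verdict re-scanned from the first look. Futility is binding:
    hitting the opposite conclusive boundary ends the search.
    """
    per_arm = plan.increment // 2
    if not plan.stochastic:
        e_int, e_ctl = round(plan.rate_int * per_arm), round(plan.rate_ctl * per_arm)
        if plan.target is Crossing.FUTILITY and e_int == 0 and e_ctl == 0:
            raise ValueError(
                "appended trials would have zero events in both arms and carry "
                "no information; widen the increment or raise the rates"
            )
        if (
            plan.target is Crossing.SUPERIORITY
            and plan.rate_int != plan.rate_ctl
            and e_int == e_ctl
        ):
            logging.getLogger(__name__).warning(
                "rounded event counts (%d vs %d per %d-patient arm) erase the "
                "assumed rate difference; consider a larger increment",
                e_int, e_ctl, per_arm,
            )

    def analyse(ds: OutcomeDataset):
        verdict, plan_k, curve = run_tsa(
            ds, plan.ris_spec, data_driven_d2=plan.data_driven_d2
        )
        return verdict

    trajectory: list[dict] = []
    verdict = analyse(plan.base)
    concl = _first_conclusive(verdict)
    if concl is plan.target:
        return FutureTrialResult(
            added_n=0, looks_added=0, terminal_crossing=concl, trajectory=()
        )
    if concl is not Crossing.NONE:
        return FutureTrialResult(
            added_n=None, looks_added=0, terminal_crossing=concl, trajectory=()
        )

    dataset = plan.base
    gen = _synthetic_trials(plan)
    added = 0
    looks = 0
    while added + plan.increment <= plan.max_added:
        dataset = dataset.with_trials_appended([next(gen)])
        added += plan.increment
        looks += 1
        verdict = analyse(dataset)
        trajectory.append(
            {
                "added_n": added,
                "ris": verdict.ris,
                "final_z": verdict.final_z,
                "crossing": verdict.crossing.value,
            }
        )
        concl = _first_conclusive(verdict)
        if concl is plan.target:
            return FutureTrialResult(
                added_n=added,
                looks_added=looks,
                terminal_crossing=concl,
                trajectory=tuple(trajectory),
            )
        if concl is not Crossing.NONE:
            return FutureTrialResult(
                added_n=None,
                looks_added=looks,
                terminal_crossing=concl,
                trajectory=tuple(trajectory),
            )
    return FutureTrialResult(
        added_n=None,
        looks_added=looks,
        terminal_crossing=Crossing.NONE,
        trajectory=tuple(trajectory),
    )
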