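"""Domain types and I/O for two-arm binary-outcome trial series.

The atomic unit is a 2x2 table (events / arm sizes for an intervention and a
control arm) plus minimal metadata; a chronologically ordered series of such
tables for one named outcome is the input to cumulative meta-analysis and
trial sequential monitoring.

The packaged fixture ``lvt_table1.csv`` holds the evidence base for direct
oral anticoagulants (DOACs, intervention) versus vitamin K antagonists (VKAs,
control) in left-ventricular thrombus: 25 studies reporting up to six
outcomes each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Design",
    "Outcome",
    "TwoByTwoTrial",
    "OutcomeDataset",
    "TrialDataError",
    "FormatError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "dataset_totals",
    "load_lvt_fixture",
]

CSV_COLUMNS = ("study_id", "year", "design", "outcome", "n_int", "e_int", "n_ctl", "e_ctl")


class TrialDataError(Exception):
    """Base class for trial-data problems."""


class FormatError(TrialDataError):
    """Input file does not match the expected tabular layout."""


class ValidationError(TrialDataError):
    """A trial violates a count invariant (e.g. events exceed arm size)."""


class Design(str, Enum):
    RCT = "RCT"
    PROSPECTIVE_OBS = "prospective_obs"
    RETROSPECTIVE_OBS = "retrospective_obs"


class Outcome(str, Enum):
    THROMBUS_RESOLUTION = "thrombus_resolution"
    STROKE = "stroke"
    ANY_THROMBOEMBOLISM = "any_thromboembolism"
    MAJOR_BLEEDING = "major_bleeding"
    ANY_BLEEDING = "any_bleeding"
    ALL_CAUSE_DEATH = "all_cause_death"

    @property
    def events_desirable(self) -> bool:
        """Whether an event counts in the intervention's favour.

        Thrombus resolution is the only outcome where more events are
        better; for all others (stroke, bleeding, death...) fewer events
        favour the intervention.
        """
        return self is Outcome.THROMBUS_RESOLUTION


@dataclass(frozen=True)
class TwoByTwoTrial:
    """One study's 2x2 outcome table.

    ``n_int``/``e_int`` are the intervention arm size and event count,
    ``n_ctl``/``e_ctl`` the control arm's.
    """

    study_id: str
    year: int
    design: Design
    n_int: int
    e_int: int
    n_ctl: int
    e_ctl: int

    def __post_init__(self) -> None:
        if self.n_int < 1 or self.n_ctl < 1:
            raise ValidationError(f"{self.study_id}: arm sizes must be >= 1")
        if not (0 <= self.e_int <= self.n_int):
            raise ValidationError(
                f"{self.study_id}: intervention events {self.e_int} outside [0, {self.n_int}]"
            )
        if not (0 <= self.e_ctl <= self.n_ctl):
            raise ValidationError(
                f"{self.study_id}: control events {self.e_ctl} outside [0, {self.n_ctl}]"
            )

    @property
    def n_total(self) -> int:
        return self.n_int + self.n_ctl

    @property
    def double_zero(self) -> bool:
        """No events in either arm: contributes patients but no effect size."""
        return self.e_int == 0 and self.e_ctl == 0

    @property
    def double_full(self) -> bool:
        """Events in every patient of both arms: likewise uninformative."""
        return self.e_int == self.n_int and self.e_ctl == self.n_ctl

    @property
    def no_information(self) -> bool:
        return self.double_zero or self.double_full

    def swapped_arms(self) -> "TwoByTwoTrial":
        """Relabel intervention as control and vice versa."""
        return replace(
            self, n_int=self.n_ctl, e_int=self.e_ctl, n_ctl=self.n_int, e_ctl=self.e_int
        )


def _sort_key(trial: TwoByTwoTrial) -> tuple[int, str]:
    return (trial.year, trial.study_id)


@dataclass(frozen=True)
class OutcomeDataset:
    """Chronologically ordered trial series for one outcome.

    Trials are canonically sorted by (year, study_id); the constructor
    sorts, so the cumulative analysis downstream never depends on input
    row order.
    """

    outcome: Outcome
    trials: tuple[TwoByTwoTrial, ...]
    events_desirable: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(sorted(self.trials, key=_sort_key)))
        if self.events_desirable is None:
            object.__setattr__(self, "events_desirable", self.outcome.events_desirable)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_int_total(self) -> int:
        return sum(t.n_int for t in self.trials)

    @property
    def n_ctl_total(self) -> int:
        return sum(t.n_ctl for t in self.trials)

    @property
    def n_total(self) -> int:
        return self.n_int_total + self.n_ctl_total

    def with_trials_appended(self, extra: Iterable[TwoByTwoTrial]) -> "OutcomeDataset":
        return OutcomeDataset(
            outcome=self.outcome,
            trials=self.trials + tuple(extra),
            events_desirable=self.events_desirable,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "study_id": t.study_id,
                    "year": t.year,
                    "design": t.design.value,
                    "outcome": self.outcome.value,
                    "n_int": t.n_int,
                    "e_int": t.e_int,
                    "n_ctl": t.n_ctl,
                    "e_ctl": t.e_ctl,
                }
                for t in self.trials
            ],
            columns=list(CSV_COLUMNS),
        )


def dataset_totals(dataset: OutcomeDataset) -> tuple[int, int, int]:
    """(intervention patients, control patients, overall) for a dataset."""
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    return dataset.n_int_total, dataset.n_ctl_total, dataset.n_total


def _datasets_from_frame(df: pd.DataFrame) -> dict[Outcome, OutcomeDataset]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    datasets: dict[Outcome, OutcomeDataset] = {}
    for outcome_label, group in df.groupby("outcome", sort=False):
        outcome = Outcome(str(outcome_label))
        trials = tuple(
            TwoByTwoTrial(
                study_id=str(row.study_id),
                year=int(row.year),
                design=Design(str(row.design)),
                n_int=int(row.n_int),
                e_int=int(row.e_int),
                n_ctl=int(row.n_ctl),
                e_ctl=int(row.e_ctl),
            )
            for row in group.itertuples(index=False)
        )
        datasets[outcome] = OutcomeDataset(outcome=outcome, trials=trials)
    return datasets


def read_trials(path: str | Path, format: str | None = None) -> dict[Outcome, OutcomeDataset]:
    """Read trial rows from CSV or JSON into one dataset per outcome.

    CSV: UTF-8, comma-separated, header with the eight canonical columns.
    JSON: mapping of outcome label -> array of trial objects with the
    remaining seven fields.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype={"study_id": str})
        if df.empty and not set(CSV_COLUMNS) <= set(df.columns):
            raise FormatError(
                f"missing column(s): {', '.join(c for c in CSV_COLUMNS if c not in df.columns)}"
            )
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not isinstance(payload, Mapping):
            raise FormatError("JSON root must be an object keyed by outcome label")
        rows = []
        for outcome_label, trials in payload.items():
            for obj in trials:
                rows.append({"outcome": outcome_label, **obj})
        df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    else:
        raise ValueError(f"unknown format {format!r}")
    return _datasets_from_frame(df)


def write_trials(
    datasets: Iterable[OutcomeDataset], path: str | Path, format: str | None = None
) -> None:
    """Write datasets in the same dialect ``read_trials`` consumes."""
    path = Path(path)
    datasets = list(datasets)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        frames = [ds.to_frame() for ds in datasets]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=list(CSV_COLUMNS))
        df.to_csv(path, index=False)
    elif format == "json":
        payload = {
            ds.outcome.value: [
                {k: v for k, v in rec.items() if k != "outcome"}
                for rec in ds.to_frame().to_dict(orient="records")
            ]
            for ds in datasets
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_lvt_fixture() -> dict[Outcome, OutcomeDataset]:
    """The packaged left-ventricular-thrombus evidence base (DOAC vs VKA)."""
    ref = resources.files("tsameta.data").joinpath("lvt_table1.csv")
    with resources.as_file(ref) as path:
        return read_trials(path, format="csv")
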