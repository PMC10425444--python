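"""Matplotlib views of a trial sequential analysis.

Renders the standard TSA picture — cumulative Z-curve against accrued
patients, spending boundaries, the fixed-sample +-1.96 lines and the
required-information-size marker — and a simple forest plot for the
conventional meta-analysis.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .boundaries import MonitoringPlan
from .meta_engine import CumulativePoint, forest_table
from .trial_data import OutcomeDataset

__all__ = ["plot_tsa", "plot_forest"]


def plot_tsa(
    curve: Sequence[CumulativePoint],
    plan: MonitoringPlan,
    title: str = "",
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Z-curve with superiority/futility boundaries on a patient axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    n = np.array([p.cumulative_n for p in curve])
    z = np.array([p.z_signed for p in curve])
    sup = np.asarray(plan.sup_bounds)
    shown = sup <= 8  # hide capped early boundaries off the top of the plot

    ax.plot(n, z, "s-", color="tab:blue", ms=4, lw=1.5, label="cumulative Z")
    ax.plot(n[shown], sup[shown], "-", color="tab:red", lw=1.2, label="superiority boundary")
    ax.plot(n[shown], -sup[shown], "-", color="tab:red", lw=1.2)
    fut_n = [ni for ni, f in zip(n, plan.fut_bounds) if f is not None]
    fut_v = [f for f in plan.fut_bounds if f is not None]
    if fut_v:
        ax.plot(fut_n, fut_v, "-", color="tab:orange", lw=1.2, label="futility boundary")
        ax.plot(fut_n, [-f for f in fut_v], "-", color="tab:orange", lw=1.2)
    ax.axhline(plan.traditional, color="gray", ls="--", lw=0.8, label="traditional $\\pm$1.96")
    ax.axhline(-plan.traditional, color="gray", ls="--", lw=0.8)
    ax.axhline(0, color="black", lw=0.6)
    if plan.ris >= n.max() * 0.8:
        ax.axvline(plan.ris, color="darkred", ls=":", lw=1.2, label=f"RIS = {plan.ris}")
    ax.set_xlabel("accrued patients")
    ax.set_ylabel("Z (favours intervention $\\uparrow$)")
    ax.set_ylim(-6, 6)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_forest(dataset: OutcomeDataset, ax: plt.Axes | None = None) -> plt.Axes:
    """Per-study odds ratios with 95% CIs and the pooled random-effects row."""
    tab = forest_table(dataset).dropna(subset=["or"])
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1))
    y = np.arange(len(tab))[::-1]
    for yi, (_, row) in zip(y, tab.iterrows()):
        pooled = row["study_id"] == "RE pooled"
        color = "tab:red" if pooled else "tab:blue"
        ax.plot(
            [row["ci_low"], row["ci_high"]], [yi, yi], "-", color=color, lw=1.2
        )
        ax.plot([row["or"]], [yi], "D" if pooled else "s", color=color, ms=6)
    ax.axvline(1.0, color="gray", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(tab["study_id"])
    ax.set_xlabel("odds ratio (log scale)")
    ax.set_title(dataset.outcome.value)
    return ax
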