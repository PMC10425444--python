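"""Alpha- and beta-spending monitoring boundaries at arbitrary looks.

Trial sequential analysis treats each added study as an interim look at a
Brownian-motion statistic B(t) observed at information fractions
t_k = (accrued patients) / (required information size).  The two-sided
superiority boundary at each look spends the O'Brien-Fleming-type
Lan-DeMets alpha budget

    alpha*(t) = 2 (1 - Phi(z_{1-alpha/2} / sqrt(t))),

which is ~0 early and reaches alpha at t = 1; the futility (inner-wedge)
boundary spends the type-II budget beta = 1 - power with the same spending
shape, evaluated under the design alternative where B drifts with mean
(z_{1-alpha/2} + z_{power}) t.

Boundary values solve first-crossing-probability equations over the joint
distribution of (B(t_1), ..., B(t_k)).  This is computed by the classic
recursive numerical integration scheme: propagate the sub-density of
not-yet-stopped paths on a trapezoid grid, and bisect on each look's
boundary until the new crossing probability equals that look's spending
increment.  Fractions above 1 spend nothing further; their boundaries are
held at the t = 1 values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "MonitoringPlan",
    "obf_spending",
    "superiority_boundaries",
    "futility_boundaries",
    "build_monitoring_plan",
]

TRADITIONAL_Z = 1.959963984540054  # fixed-sample two-sided 5% line

# numerical scheme defaults: trapezoid grid spanning +-8 SD, >=512 nodes,
# boundary bisection tolerance 1e-6; boundaries capped at Z = 8
GRID_NODES = 512
GRID_SD_SPAN = 8.0
BISECT_TOL = 1e-6
Z_CAP = 8.0


def obf_spending(t: float, alpha: float) -> float:
    """O'Brien-Fleming-type Lan-DeMets error spent by information fraction t.

    Two-sided total; equals ``alpha`` at t = 1 and vanishes as t -> 0+.
    """
    if t <= 0:
        raise ValueError(f"information fraction must be positive, got {t}")
    t = min(t, 1.0)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(2.0 * stats.norm.sf(z / math.sqrt(t)))


class _StoppedDensity:
    """Sub-density of sequential-statistic paths that have not yet crossed.

    Works on the Brownian (B) scale under a linear drift: B(t) ~ N(theta*t, t).
    ``step`` advances time; crossing probabilities against candidate
    boundaries are evaluated against the *current* state before stepping.
    """

    def __init__(self, drift: float, n_nodes: int = GRID_NODES):
        self.theta = drift
        self.n_nodes = n_nodes
        self.t = 0.0
        self.x = np.array([0.0])
        self.f = np.array([1.0])
        self.w = np.array([1.0])  # quadrature weights

    def _increment(self, t_new: float) -> tuple[float, float]:
        dt = t_new - self.t
        if dt <= 0:
            raise ValueError("time must strictly increase between steps")
        return dt, self.theta * dt

    def prob_above(self, b: float, t_new: float) -> float:
        """P(no crossing before, B(t_new) >= b)."""
        dt, mu = self._increment(t_new)
        tail = stats.norm.sf((b - self.x - mu) / math.sqrt(dt))
        return float(np.sum(self.w * self.f * tail))

    def prob_below(self, b: float, t_new: float) -> float:
        """P(no crossing before, B(t_new) <= b)."""
        dt, mu = self._increment(t_new)
        tail = stats.norm.cdf((b - self.x - mu) / math.sqrt(dt))
        return float(np.sum(self.w * self.f * tail))

    def step(self, t_new: float, lower: float | None, upper: float | None) -> None:
        """Advance to t_new, truncating the density to (lower, upper)."""
        dt, mu = self._increment(t_new)
        sd = math.sqrt(dt)
        mean_now = self.theta * t_new
        sd_now = math.sqrt(t_new)
        lo = mean_now - GRID_SD_SPAN * sd_now if lower is None else lower
        hi = mean_now + GRID_SD_SPAN * sd_now if upper is None else upper
        lo = max(lo, mean_now - GRID_SD_SPAN * sd_now, float(self.x.min()) + mu - GRID_SD_SPAN * sd)
        hi = min(hi, mean_now + GRID_SD_SPAN * sd_now, float(self.x.max()) + mu + GRID_SD_SPAN * sd)
        if hi <= lo:  # wedge closed: no surviving paths
            self.t = t_new
            self.x = np.array([0.5 * (lo + hi)])
            self.f = np.array([0.0])
            self.w = np.array([1.0])
            return
        y = np.linspace(lo, hi, self.n_nodes)
        kernel = stats.norm.pdf((y[:, None] - self.x[None, :] - mu) / sd) / sd
        f_new = kernel @ (self.w * self.f)
        dx = y[1] - y[0]
        w_new = np.full(self.n_nodes, dx)
        w_new[0] = w_new[-1] = dx / 2
        self.t, self.x, self.f, self.w = t_new, y, f_new, w_new


def _clamp_fractions(info_fractions: Sequence[float]) -> np.ndarray:
    t = np.asarray(info_fractions, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("info_fractions must be a non-empty 1-D sequence")
    if np.any(t <= 0):
        raise ValueError("information fractions must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("information fractions must be strictly increasing")
    return np.minimum(t, 1.0)


def superiority_boundaries(
    info_fractions: Sequence[float],
    alpha: float = 0.05,
    n_nodes: int = GRID_NODES,
) -> np.ndarray:
    """Two-sided symmetric alpha-spending boundaries on the Z scale.

    Solves, look by look, for u_k with
    P_H0(first crossing |Z_j| >= u_j at look k) equal to the spending
    increment.  Each side is computed as a one-sided problem at level
    alpha/2 with the O'Brien-Fleming-shaped spending function (the
    convention of the published Lan-DeMets boundary tables; the two-sided
    crossing overlap is negligible under this spending).  Boundaries are
    capped at Z = 8: looks whose spending increment is smaller than the
    crossing probability at the cap report the cap.
    """
    t = _clamp_fractions(info_fractions)
    dens = _StoppedDensity(drift=0.0, n_nodes=n_nodes)
    bounds: list[float] = []
    spent = 0.0
    for k, tk in enumerate(t):
        if k > 0 and tk == t[k - 1]:  # beyond full information: hold value
            bounds.append(bounds[-1])
            continue
        target = obf_spending(tk, alpha / 2.0) - spent
        sd = math.sqrt(tk)
        cap_b = Z_CAP * sd
        p_cap = dens.prob_above(cap_b, tk)
        if p_cap >= target:
            u_b = cap_b
            spent += p_cap
        else:
            u_b = brentq(
                lambda b: dens.prob_above(b, tk) - target,
                0.0,
                cap_b,
                xtol=BISECT_TOL * sd,
            )
            spent += target
        bounds.append(u_b / sd)
        dens.step(tk, lower=None, upper=u_b)
    return np.asarray(bounds)


def futility_boundaries(
    info_fractions: Sequence[float],
    alpha: float = 0.05,
    power: float = 0.80,
    drift: float | None = None,
    sup_bounds: Sequence[float] | None = None,
    n_nodes: int = GRID_NODES,
) -> list[float | None]:
    """Inner (futility) boundaries on the Z scale, ``None`` where undefined.

    Spends the type-II budget beta = 1 - power with the same
    O'Brien-Fleming-type shape, under the design alternative where the
    Brownian statistic has mean ``drift * t`` (default drift
    z_{1-alpha/2} + z_{power}).  Paths are confined below the superiority
    boundary; at each look the inner bound f_k makes the probability of
    dropping below it match the beta increment.  Early looks where the
    solution would be non-positive report ``None`` (the wedge has not
    opened); the wedge never exceeds the superiority boundary.
    """
    if drift is None:
        drift = float(stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power))
    if drift <= 0:
        raise ValueError("drift must be positive")
    beta = 1.0 - power
    t = _clamp_fractions(info_fractions)
    if sup_bounds is None:
        sup_bounds = superiority_boundaries(info_fractions, alpha, n_nodes=n_nodes)
    sup_bounds = np.asarray(sup_bounds, dtype=float)
    if len(sup_bounds) != len(t):
        raise ValueError("sup_bounds must match info_fractions in length")

    dens = _StoppedDensity(drift=drift, n_nodes=n_nodes)
    fut: list[float | None] = []
    spent = 0.0
    for k, tk in enumerate(t):
        sd = math.sqrt(tk)
        u_b = min(sup_bounds[k], Z_CAP) * sd
        if k > 0 and tk == t[k - 1]:  # beyond full information: hold value
            fut.append(fut[-1])
            continue
        target = obf_spending(tk, beta) - spent
        p_at_zero = dens.prob_below(0.0, tk)
        if p_at_zero >= target:
            # solution would be <= 0 on the Z scale: futility not yet tested
            fut.append(None)
            dens.step(tk, lower=None, upper=u_b)
            continue
        p_at_up = dens.prob_below(u_b, tk)
        if p_at_up <= target:
            # even the full remaining mass cannot spend the increment:
            # the wedge closes onto the superiority boundary
            f_b = u_b
            spent += p_at_up
        else:
            f_b = brentq(
                lambda b: dens.prob_below(b, tk) - target,
                0.0,
                u_b,
                xtol=BISECT_TOL * sd,
            )
            spent += target
        fut.append(f_b / sd)
        dens.step(tk, lower=f_b, upper=u_b)
    return fut


@dataclass(frozen=True)
class MonitoringPlan:
    """Boundary values anchored to a required information size.

    ``info_fractions`` are accrued patients / RIS at each look (may exceed
    1); ``sup_bounds`` and ``fut_bounds`` are on the Z scale, with ``None``
    futility entries at looks where the wedge is not open.
    """

    info_fractions: tuple[float, ...]
    alpha: float
    power: float
    drift: float
    sup_bounds: tuple[float, ...]
    fut_bounds: tuple[float | None, ...]
    ris: int
    traditional: float = field(default=TRADITIONAL_Z)

    def __post_init__(self) -> None:
        k = len(self.info_fractions)
        if len(self.sup_bounds) != k or len(self.fut_bounds) != k:
            raise ValueError("boundary sequences must match info_fractions in length")

    @property
    def n_looks(self) -> int:
        return len(self.info_fractions)

    def to_json_dict(self) -> dict:
        return {
            "ris": self.ris,
            "alpha": self.alpha,
            "power": self.power,
            "drift": self.drift,
            "info_fractions": list(self.info_fractions),
            "sup_bounds": list(self.sup_bounds),
            "fut_bounds": list(self.fut_bounds),
            "traditional": self.traditional,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "MonitoringPlan":
        return cls(
            info_fractions=tuple(d["info_fractions"]),
            alpha=d["alpha"],
            power=d["power"],
            drift=d["drift"],
            sup_bounds=tuple(d["sup_bounds"]),
            fut_bounds=tuple(None if b is None else b for b in d["fut_bounds"]),
            ris=int(d["ris"]),
            traditional=d.get("traditional", TRADITIONAL_Z),
        )


def build_monitoring_plan(
    cumulative_n: Sequence[int],
    ris: int,
    alpha: float = 0.05,
    power: float = 0.80,
    with_futility: bool = True,
    n_nodes: int = GRID_NODES,
) -> MonitoringPlan:
    """Boundaries for looks placed at the given cumulative patient counts."""
    if ris < 1:
        raise ValueError("ris must be a positive integer")
    cn = np.asarray(cumulative_n, dtype=float)
    if np.any(np.diff(cn) <= 0) or np.any(cn <= 0):
        raise ValueError("cumulative_n must be positive and strictly increasing")
    fractions = cn / ris
    drift = float(stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power))
    sup = superiority_boundaries(fractions, alpha, n_nodes=n_nodes)
    if with_futility:
        fut = futility_boundaries(
            fractions, alpha, power, drift=drift, sup_bounds=sup, n_nodes=n_nodes
        )
    else:
        fut = [None] * len(sup)
    return MonitoringPlan(
        info_fractions=tuple(float(f) for f in fractions),
        alpha=alpha,
        power=power,
        drift=drift,
        sup_bounds=tuple(float(u) for u in sup),
        fut_bounds=tuple(fut),
        ris=ris,
    )
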