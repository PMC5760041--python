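"""Catchability, catch, and Smith entry-exit effort dynamics.

Catchability is density dependent:

    q(D) = (a*D + b) / (c_i * D),   clamped below at zero,

a rectangular hyperbola in CPUE-density space.  Because ``c_i = area_i * w``
and ``B_i = N_i * w``, the per-trip wet catch is ``q * B_i = a*D + b`` kg:
nearly flat at high density (hyperstable CPUE) and collapsing to zero below
``D = -b/a`` (~0.01 ind m^-2).

Fleet size follows a Smith (entry-exit) rule: the day-to-day change in total
effort is proportional, via the responsiveness parameter phi, to the mean
per-trip quasi-profit minus the opportunity cost of the best alternative
fishery.  Effort is allocated across density levels in proportion to the
previous day's per-trip quasi-profit, and a level receives no effort once
its quasi-profit falls to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CatchabilityParams",
    "FleetParams",
    "catchability",
    "catch_individuals",
    "allocate_effort",
    "update_fleet",
]


@dataclass(frozen=True)
class CatchabilityParams:
    """Parameters of the density-dependent catchability relation.

    ``a`` is the slope of per-trip catch against density (kg per ind m^-2
    per trip) and ``b`` its intercept (kg per trip, negative: searching stops
    paying below D = -b/a).  The per-level scale constant c_i lives with the
    population state.
    """

    a: float = 1527.7
    b: float = -15.3

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("parameter a must be positive")


@dataclass(frozen=True)
class FleetParams:
    """Smith entry-exit fleet parameters."""

    initial_effort: float = 691.0    # trips day^-1 at the season opening
    max_effort: float = 691.0        # licensed fleet ceiling, trips day^-1
    phi: float = 0.10                # entry-exit responsiveness, trips US$^-1
    #   (calibrated to the observed cessation of effort under this package's
    #   reconstructed price/cost sub-models; see docs/methods.md)
    opportunity_cost: float = 85.0   # US$ per trip from the best alternative
    allocation_basis: str = "quasi_profit_then_revenue"
    # Spatial split of the day's trips: "quasi_profit" (strictly rational —
    # loss-making grounds are abandoned at once and fishing stops abruptly
    # when none is profitable), "revenue" (boats follow gross income
    # regardless of margin), or the default "quasi_profit_then_revenue":
    # profitable grounds are preferred while any exists; once none covers
    # its costs the still-active fleet follows income while the entry-exit
    # dynamic unwinds participation.
    gravity: bool = True
    # Weight each ground's income signal by its available biomass (a gravity
    # model of fleet distribution).  Without it, a tiny high-density core
    # attracts a fleet large enough to strip it in days, which real
    # crowding/interference prevents.

    def __post_init__(self) -> None:
        if self.initial_effort < 0 or self.max_effort < 0:
            raise ValueError("effort levels must be non-negative")
        if self.initial_effort > self.max_effort:
            raise ValueError("initial effort exceeds the fleet ceiling")
        if self.allocation_basis not in ("revenue", "quasi_profit",
                                         "quasi_profit_then_revenue"):
            raise ValueError("allocation_basis must be 'revenue', 'quasi_profit'"
                             " or 'quasi_profit_then_revenue'")


def catchability(density: np.ndarray | float, c: np.ndarray | float,
                 params: CatchabilityParams) -> np.ndarray | float:
    """Density-dependent catchability q = max(0, (a*D + b) / (c_i * D)).

    Returns 0 at D = 0 (nothing to find, no trip removes anything).
    """
    d = np.asarray(density, dtype=float)
    c = np.asarray(c, dtype=float)
    if (c <= 0).any():
        raise ValueError("c_i must be positive")
    if (d < 0).any():
        raise ValueError("density must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (params.a * d + params.b) / (c * d)
    q = np.where(d > 0, np.maximum(q, 0.0), 0.0)
    return q if q.ndim else float(q)


def catch_individuals(f: np.ndarray | float, q: np.ndarray | float,
                      n: np.ndarray | float) -> np.ndarray | float:
    """Catch Y = q * f * N, capped at the available abundance N."""
    f = np.asarray(f, dtype=float)
    q = np.asarray(q, dtype=float)
    n = np.asarray(n, dtype=float)
    if (f < 0).any() or (q < 0).any() or (n < 0).any():
        raise ValueError("effort, catchability and abundance must be >= 0")
    y = np.minimum(q * f * n, n)
    return y if y.ndim else float(y)


def allocate_effort(total_effort: float,
                    per_trip_profit: np.ndarray) -> np.ndarray:
    """Split total daily effort across levels, proportional to quasi-profit.

    Levels whose previous-day per-trip quasi-profit is non-positive get no
    effort (fishers stop visiting unprofitable grounds).  If no level is
    profitable the allocation is all zero — effort stays ashore.
    """
    if total_effort < 0:
        raise ValueError("total effort must be non-negative")
    p = np.asarray(per_trip_profit, dtype=float)
    weights = np.where(np.isfinite(p) & (p > 0), p, 0.0)
    s = weights.sum()
    if s <= 0 or total_effort == 0:
        return np.zeros_like(weights)
    return total_effort * weights / s


def update_fleet(effort: float, profit_signal: float, phi: float,
                 max_effort: float) -> float:
    """Smith entry-exit update: F(t+1) = clamp(F(t) + phi*signal, 0, F_max).

    ``profit_signal`` is the realized mean per-trip quasi-profit minus the
    opportunity cost; positive signals attract effort up to the licensed
    ceiling, negative signals drive exit.
    """
    if not 0 <= effort <= max_effort:
        raise ValueError("effort must lie in [0, max_effort]")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    return float(np.clip(effort + phi * profit_signal, 0.0, max_effort))
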