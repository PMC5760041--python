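"""Fishery economics: ex-vessel price, trip costs, quasi-profits, NPV.

Quasi-profit (Eq. pi = f * (p * q * B - c)) counts only variable costs —
fuel, crew meals, ice — and is the short-run signal fishers respond to.
The ex-vessel price is a linear inverse demand in the day's total gutted
landings; fuel cost rises as density falls because search time grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EconomicParams", "ex_vessel_price", "trip_cost", "per_trip_profit",
           "quasi_profit", "npv"]


@dataclass(frozen=True)
class EconomicParams:
    """Price, cost and discounting parameters.

    price_intercept / price_slope define the inverse demand
    ``price = intercept + slope * landings`` on the US$-per-tonne (gutted)
    scale, with landings in tonnes gutted per day.  gas_alpha + gas_beta / D
    is the fuel cost per trip; other_variable_cost covers crew meals and ice.
    """

    price_intercept: float = 5486.0      # US$ per tonne gutted at zero supply
    price_slope: float = -10.4           # US$ per tonne per (tonne day^-1)
    price_quantity_basis: str = "wet"    # demand slope acts on "wet" (landed
    #   whole; evisceration on board is prohibited) or "gutted" tonnes
    gas_alpha: float = 52.5              # US$ per trip, density-independent
    gas_beta: float = 5.2                # US$ (ind m^-2) per trip, search term
    other_variable_cost: float = 40.0    # US$ per trip (meals + ice)
    gutted_fraction: float = 0.6         # gutted weight / wet weight
    annual_discount_rate: float = 0.10
    opportunity_cost: float = 85.0       # US$ per trip, alternative fishery

    def __post_init__(self) -> None:
        if not 0 < self.gutted_fraction <= 1:
            raise ValueError("gutted_fraction must be in (0, 1]")
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.price_quantity_basis not in ("wet", "gutted"):
            raise ValueError("price_quantity_basis must be 'wet' or 'gutted'")


def ex_vessel_price(daily_landings_t: float, params: EconomicParams) -> float:
    """Ex-vessel price in US$ per kg gutted, clamped at zero.

    ``daily_landings_t`` is the day's total landings delivered to buyers, in
    tonnes on the configured quantity basis (``price_quantity_basis``): wet
    weight as landed whole, or gutted weight.
    """
    if daily_landings_t < 0:
        raise ValueError("landings must be non-negative")
    per_tonne = params.price_intercept + params.price_slope * daily_landings_t
    return max(0.0, per_tonne) / 1000.0


def trip_cost(density: np.ndarray | float,
              params: EconomicParams) -> np.ndarray | float:
    """Variable cost of one trip at local density D (US$).

    cost = gas_alpha + gas_beta / D + other_variable_cost; the 1/D term
    captures the longer search at low density.  D must be positive — no
    trips happen on bare ground.
    """
    d = np.asarray(density, dtype=float)
    if (d <= 0).any():
        raise ValueError("density must be positive to cost a trip")
    cost = params.gas_alpha + params.gas_beta / d + params.other_variable_cost
    return cost if cost.ndim else float(cost)


def per_trip_profit(density: np.ndarray, per_trip_catch_wet_kg: np.ndarray,
                    price_gutted_kg: float,
                    params: EconomicParams) -> np.ndarray:
    """Quasi-profit of a single trip at each level (US$ per trip).

    Revenue chain: wet kg caught -> gutted kg (x gutted_fraction) ->
    US$ (x price).  Levels with zero density earn -inf so they can never
    attract effort.
    """
    d = np.asarray(density, dtype=float)
    y = np.asarray(per_trip_catch_wet_kg, dtype=float)
    out = np.full(d.shape, -np.inf)
    pos = d > 0
    revenue = price_gutted_kg * params.gutted_fraction * y[pos]
    out[pos] = revenue - trip_cost(d[pos], params)
    return out


def quasi_profit(f: float, price_gutted_kg: float, q: float, biomass_kg: float,
                 cost_per_trip: float, gutted_fraction: float) -> float:
    """Level quasi-profit pi = f * (p * gutted_fraction * q * B - c) (US$)."""
    if min(f, price_gutted_kg, q, biomass_kg) < 0:
        raise ValueError("inputs must be non-negative")
    return f * (price_gutted_kg * gutted_fraction * q * biomass_kg - cost_per_trip)


def npv(daily_profits: np.ndarray, annual_rate: float,
        days: np.ndarray | None = None) -> float:
    """Net present value of a daily quasi-profit stream (US$).

    Each day's profit is discounted as ``pi_t / (1 + rate)^(t / 365)`` with
    ``t`` the 1-based day index (or an explicit ``days`` vector).
    """
    if annual_rate < 0:
        raise ValueError("rate must be non-negative")
    pi = np.asarray(daily_profits, dtype=float)
    if days is None:
        days = np.arange(1, pi.size + 1)
    days = np.asarray(days, dtype=float)
    return float(np.sum(pi / (1.0 + annual_rate) ** (days / 365.0)))
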